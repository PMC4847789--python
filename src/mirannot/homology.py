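"""Homology-based annotation of known hairpins and cross-species search.

Reference (miRBase-style) hairpins are located on a genome by seeded,
ungapped local alignment; hits are retained on length and identity (the
desk-scale replacement for a BLASTN e-value cutoff), then confirmed by
requiring a mature sequence to align inside the hit with at most one
mismatch.  The same machinery, run against a second genome, looks for
homologues of novel hairpins and compares their genomic context labels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import pandas as pd

from .align import SeedIndex
from .intervals import GenomicInterval
from .sequences import revcomp

MIN_HIT_LEN = 60
MIN_IDENTITY = 0.8
_SEED_LEN = 12
_SEED_STEP = 6
_MISMATCH_PENALTY = 2  # Kadane scoring: match +1, mismatch -2


@dataclass(frozen=True)
class HomologyHit:
    """A retained genomic hit of one reference hairpin."""

    query_id: str
    locus: GenomicInterval
    alignment_length: int
    identity: float
    mature_confirmed: bool = False
    mature_mismatches: int | None = None


def _best_segment(matches: Sequence[bool]) -> tuple[int, int, int]:
    """Maximum-scoring contiguous segment: (start, length, n_matches)."""
    best = (0, 0, 0)
    score = 0.0
    seg_start = 0
    seg_matches = 0
    best_score = 0.0
    for i, m in enumerate(matches):
        gain = 1 if m else -_MISMATCH_PENALTY
        if score <= 0:
            score, seg_start, seg_matches = 0, i, 0
        score += gain
        seg_matches += 1 if m else 0
        if score > best_score:
            best_score = score
            best = (seg_start, i - seg_start + 1, seg_matches)
        elif score <= 0:
            seg_matches = 0
    return best


def map_hairpins(
    query_hairpins: Mapping[str, str],
    genome: Mapping[str, str] | SeedIndex,
    min_len: int = MIN_HIT_LEN,
    min_identity: float = MIN_IDENTITY,
) -> list[HomologyHit]:
    """Seeded ungapped local hits of each hairpin, both strands.

    Hits are the maximum-scoring contiguous segment around each seed
    anchor, retained iff segment length >= ``min_len`` and identity >=
    ``min_identity``.
    """
    index = genome if isinstance(genome, SeedIndex) else SeedIndex(genome)
    hits: dict[tuple[str, str, int, int, str], HomologyHit] = {}
    for qid, qseq in sorted(query_hairpins.items()):
        if len(qseq) < min_len:
            raise ValueError(
                f"query {qid}: length {len(qseq)} below min_len {min_len}"
            )
        for strand, q in (("+", qseq), ("-", revcomp(qseq))):
            anchors: set[tuple[str, int]] = set()
            offsets = list(range(0, len(q) - _SEED_LEN + 1, _SEED_STEP))
            for off in offsets:
                seed = q[off : off + _SEED_LEN]
                for chrom in index.targets:
                    for g, _mm in index._find_one_strand(chrom, seed, 0):
                        anchors.add((chrom, g - off))
            for chrom, start in sorted(anchors):
                tseq = index.targets[chrom]
                lo = max(0, start)
                hi = min(len(tseq), start + len(q))
                if hi - lo < min_len:
                    continue
                qs = q[lo - start : hi - start]
                ts = tseq[lo:hi]
                seg_off, seg_len, seg_match = _best_segment(
                    [a == b for a, b in zip(qs, ts)]
                )
                if seg_len < min_len:
                    continue
                identity = seg_match / seg_len
                if identity < min_identity:
                    continue
                iv = GenomicInterval(chrom, lo + seg_off, lo + seg_off + seg_len, strand)
                key = (qid, chrom, iv.start, iv.end, strand)
                prev = hits.get(key)
                if prev is None or identity > prev.identity:
                    hits[key] = HomologyHit(qid, iv, seg_len, identity)
    return sorted(hits.values(), key=lambda h: (h.query_id, h.locus))


def _scan_mismatches(query: str, target: str, max_mm: int) -> int | None:
    """Best (minimum) mismatch count of query fully inside target, or None."""
    best: int | None = None
    L = len(query)
    for start in range(0, len(target) - L + 1):
        mm = 0
        for a, b in zip(query, target[start : start + L]):
            if a != b:
                mm += 1
                if mm > max_mm:
                    break
        else:
            if best is None or mm < best:
                best = mm
                if best == 0:
                    return 0
    return best


def confirm_mature(
    hit: HomologyHit,
    mature_seqs: Sequence[str],
    genome: Mapping[str, str],
    max_mismatch: int = 1,
) -> HomologyHit:
    """Set mature_confirmed iff some mature aligns fully inside the hit
    locus with at most ``max_mismatch`` substitutions (no gaps)."""
    locus_seq = genome[hit.locus.chrom][hit.locus.start : hit.locus.end]
    best: int | None = None
    for mature in mature_seqs:
        for q in (mature, revcomp(mature)):
            mm = _scan_mismatches(q, locus_seq, max_mismatch)
            if mm is not None and (best is None or mm < best):
                best = mm
    return replace(hit, mature_confirmed=best is not None, mature_mismatches=best)


def split_known_novel(
    candidate_loci: Sequence[GenomicInterval],
    conserved_loci: Sequence[GenomicInterval],
    existing_annotation: Sequence[GenomicInterval],
) -> dict[str, list[GenomicInterval]]:
    """Partition candidates against the conserved set (>=1 bp, strand-blind).

    Returns ``conserved`` (candidates overlapping a confirmed homology
    locus), ``novel`` (candidates overlapping none), and
    ``newly_annotated`` (conserved loci absent from the existing
    annotation).
    """
    conserved, novel = [], []
    for cand in candidate_loci:
        if any(cand.overlaps(c) for c in conserved_loci):
            conserved.append(cand)
        else:
            novel.append(cand)
    newly = [
        c for c in conserved_loci if not any(c.overlaps(e) for e in existing_annotation)
    ]
    return {"conserved": conserved, "novel": novel, "newly_annotated": newly}


def find_cross_species_homologs(
    novel_hairpins: Mapping[str, str],
    other_genome: Mapping[str, str],
    other_features: Mapping[str, Sequence[GenomicInterval]],
    matures_by_id: Mapping[str, Sequence[str]],
    source_context_by_id: Mapping[str, str],
    min_len: int = MIN_HIT_LEN,
    min_identity: float = MIN_IDENTITY,
    min_context_fraction: float = 0.15,
) -> pd.DataFrame:
    """Homologues of novel hairpins in a second genome, mature-confirmed.

    Hits whose source matures do not align with <= 1 mismatch are dropped.
    Each retained row reports the locus, the source locus id and the
    genomic context label in both species.
    """
    from .context import classify_locus  # local import: avoids a cycle

    hits = map_hairpins(novel_hairpins, other_genome, min_len, min_identity)
    rows = []
    for hit in hits:
        hit = confirm_mature(hit, matures_by_id.get(hit.query_id, ()), other_genome)
        if not hit.mature_confirmed:
            continue
        label = classify_locus(hit.locus, other_features, min_context_fraction)
        rows.append(
            {
                "chrom": hit.locus.chrom,
                "start": hit.locus.start,
                "end": hit.locus.end,
                "strand": hit.locus.strand,
                "source_locus": hit.query_id,
                "alignment_length": hit.alignment_length,
                "identity": round(hit.identity, 4),
                "mature_mismatches": hit.mature_mismatches,
                "source_context": source_context_by_id.get(hit.query_id, ""),
                "target_context": label.category,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "strand", "source_locus",
            "alignment_length", "identity", "mature_mismatches",
            "source_context", "target_context",
        ],
    )
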
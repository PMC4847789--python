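"""Genomic context of annotated loci: classification and miRtron calling.

Hairpins are labelled UTR, EXON, INTRON or INTERGENIC by overlap with the
gene annotation (at least 15% of the hairpin length, precedence
UTR > EXON > INTRON; UTRs lie within exons, so UTR-first keeps the UTR
category distinct).  Overlap is strand-blind; the host feature is
recorded for reporting.  miRtrons are short introns (50-120 bp) almost
fully covered by a hairpin, with the two read peaks anchored at the
intron ends up to a short trimmed tail.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .align import ReadAlignment
from .intervals import GenomicInterval, intersect, merge_intervals, subtract  # noqa: F401  (re-exported set ops)
from .io import GeneModel

CONTEXT_PRECEDENCE = ("UTR", "EXON", "INTRON")
MIRTRON_LEN_RANGE = (50, 120)
MIRTRON_MIN_COVERAGE = 0.95
MIRTRON_TAIL_MAX = 3


@dataclass(frozen=True)
class ContextLabel:
    category: str  # UTR | EXON | INTRON | INTERGENIC
    overlap_fraction: float
    host: str | None = None
    hairpin_id: str = ""


@dataclass(frozen=True)
class MirtronCall:
    hairpin_id: str
    intron: GenomicInterval
    intron_coverage: float
    end5_offset: int
    end3_offset: int


def derive_introns(gene_models: Iterable[GeneModel]) -> dict[str, list[GenomicInterval]]:
    """Gaps between consecutive exons of each transcript, strand inherited."""
    out: dict[str, list[GenomicInterval]] = {}
    for model in gene_models:
        model.validate()
        introns = [
            GenomicInterval(model.chrom, a.end, b.start, model.strand)
            for a, b in zip(model.exons, model.exons[1:])
            if b.start > a.end
        ]
        out[model.transcript_id] = introns
    return out


def annotation_features(
    gene_models: Iterable[GeneModel],
) -> dict[str, list[tuple[GenomicInterval, str]]]:
    """Per-category (interval, transcript_id) lists: UTR, EXON, INTRON.

    CDS rows count as exonic; UTR rows are kept as their own category.
    """
    models = list(gene_models)
    feats: dict[str, list[tuple[GenomicInterval, str]]] = {
        "UTR": [],
        "EXON": [],
        "INTRON": [],
    }
    for m in models:
        for u in m.utr5 + m.utr3:
            feats["UTR"].append((u, m.transcript_id))
        for e in m.exons + m.cds:
            feats["EXON"].append((e, m.transcript_id))
    for tid, introns in derive_introns(models).items():
        for iv in introns:
            feats["INTRON"].append((iv, tid))
    return feats


def classify_locus(
    locus: GenomicInterval,
    features: Mapping[str, Sequence[tuple[GenomicInterval, str] | GenomicInterval]],
    min_fraction: float = 0.15,
) -> ContextLabel:
    """Context category by >= ``min_fraction`` overlap of the hairpin length."""
    for category in CONTEXT_PRECEDENCE:
        entries = features.get(category, ())
        pairs = [e if isinstance(e, tuple) else (e, None) for e in entries]
        touching = [(iv, host) for iv, host in pairs if locus.overlaps(iv)]
        if not touching:
            continue
        covered = merge_intervals([iv for iv, _ in touching])
        overlap = sum(locus.overlap_len(iv) for iv in covered)
        fraction = overlap / locus.length
        if fraction >= min_fraction:
            host = max(touching, key=lambda t: locus.overlap_len(t[0]))[1]
            return ContextLabel(category, fraction, host)
    return ContextLabel("INTERGENIC", 0.0, None)


def _intron_local_reads(
    intron: GenomicInterval, alignments: Iterable[ReadAlignment]
) -> list[tuple[int, int, int]]:
    """(5' start, 3' end (exclusive), count) in intron-local 5'->3' coords,
    for reads on the intron strand lying fully inside it."""
    out = []
    for a in alignments:
        if a.target != intron.chrom or a.strand != intron.strand:
            continue
        if a.start < intron.start or a.end > intron.end:
            continue
        if intron.strand == "-":
            out.append((intron.end - a.end, intron.end - a.start, a.count))
        else:
            out.append((a.start - intron.start, a.end - intron.start, a.count))
    return out


def detect_mirtrons(
    hairpins: Sequence[tuple[str, GenomicInterval]],
    introns: Sequence[GenomicInterval],
    alignments: Iterable[ReadAlignment],
    tail_max: int = MIRTRON_TAIL_MAX,
    window: int = 2,
    min_fraction: float = 0.75,
    min_count: int = 10,
    len_range: tuple[int, int] = MIRTRON_LEN_RANGE,
    min_coverage: float = MIRTRON_MIN_COVERAGE,
) -> list[MirtronCall]:
    """Splicing-defined miRNA calls.

    A call requires: intron length within ``len_range``; a hairpin locus
    covering >= ``min_coverage`` of the intron; and a clear 5'/3' peak
    pair whose modal arm starts/ends lie within ``tail_max`` nt of the
    intron ends (allowing a short trimmed tail), each peak holding >=
    ``min_fraction`` of its arm's reads (>= ``min_count`` reads per arm).
    """
    alignments = list(alignments)
    calls = []
    for intron in introns:
        if not (len_range[0] <= intron.length <= len_range[1]):
            continue
        best = None
        for hid, locus in hairpins:
            cov = locus.overlap_len(intron) / intron.length
            if cov >= min_coverage and (best is None or cov > best[1]):
                best = (hid, cov)
        if best is None:
            continue
        reads = _intron_local_reads(intron, alignments)
        if not reads:
            continue
        mid = intron.length / 2
        offsets = []
        ok = True
        for arm in ("5p", "3p"):
            arm_reads = [r for r in reads if (r[0] < mid) == (arm == "5p")]
            total = sum(c for _s, _e, c in arm_reads)
            if total < min_count:
                ok = False
                break
            starts = Counter()
            for s, _e, c in arm_reads:
                starts[s] += c
            modal = min(starts, key=lambda p: (-starts[p], p))
            near = sum(c for p, c in starts.items() if abs(p - modal) <= window)
            if near < min_fraction * total:
                ok = False
                break
            if arm == "5p":
                if not (0 <= modal <= tail_max):
                    ok = False
                    break
                offsets.append(modal)
            else:
                ends = Counter()
                for s, e, c in arm_reads:
                    if abs(s - modal) <= window:
                        ends[e] += c
                modal_end = min(ends, key=lambda p: (-ends[p], p))
                off3 = intron.length - modal_end
                if not (0 <= off3 <= tail_max):
                    ok = False
                    break
                offsets.append(off3)
        if ok:
            calls.append(MirtronCall(best[0], intron, best[1], offsets[0], offsets[1]))
    calls.sort(key=lambda c: (c.intron.chrom, c.intron.start))
    return calls
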
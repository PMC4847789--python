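"""Candidate precursor discovery from genome-wide read alignments.

A deliberately transparent stand-in for the published miRNA predictors:
same-strand read placements are clustered, each cluster is excised with
flanking sequence, and a window survives only if its two dominant read
stacks sit on opposite arms of a single folded stem-loop.  The candidate
is trimmed to the extent of those two stacks before folding, which keeps
the structural test about the processed hairpin rather than about noise
pairs in the flanks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .align import ReadAlignment
from .fold import FoldResult, hairpin_metrics, nussinov_fold
from .intervals import GenomicInterval, merge_intervals
from .sequences import revcomp

MIN_PRECURSOR_LEN = 50
MAX_PRECURSOR_LEN = 300


@dataclass(frozen=True)
class ReadCluster:
    """A stranded run of nearby read placements with their summed count."""

    interval: GenomicInterval
    count: int


@dataclass
class HairpinCandidate:
    """A putative precursor locus with its excised sequence and fold."""

    locus: GenomicInterval
    precursor_seq: str
    fold: FoldResult
    source: str  # DISCOVERY or HOMOLOGY
    id: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            self.id = locus_id(self.locus)
        if len(self.precursor_seq) != self.locus.length:
            raise ValueError(f"{self.id}: precursor/locus length mismatch")


def locus_id(iv: GenomicInterval) -> str:
    """Display id ``chrom/start-end(strand)`` with 1-based start."""
    return f"{iv.chrom}/{iv.start + 1}-{iv.end}({iv.strand})"


def extract_precursor(genome: Mapping[str, str], iv: GenomicInterval) -> str:
    seq = genome[iv.chrom][iv.start : iv.end]
    return revcomp(seq) if iv.strand == "-" else seq


def cluster_read_stacks(
    alignments: Iterable[ReadAlignment], max_gap: int = 65
) -> list[ReadCluster]:
    """Merge same-strand placements within ``max_gap`` into read clusters."""
    by_key: dict[tuple[str, str], list[ReadAlignment]] = {}
    for a in alignments:
        by_key.setdefault((a.target, a.strand), []).append(a)
    clusters = []
    for (chrom, strand), alns in sorted(by_key.items()):
        alns.sort(key=lambda a: (a.start, a.end))
        cur_start, cur_end, cur_count = alns[0].start, alns[0].end, alns[0].count
        for a in alns[1:]:
            if a.start <= cur_end + max_gap:
                cur_end = max(cur_end, a.end)
                cur_count += a.count
            else:
                clusters.append(
                    ReadCluster(GenomicInterval(chrom, cur_start, cur_end, strand), cur_count)
                )
                cur_start, cur_end, cur_count = a.start, a.end, a.count
        clusters.append(
            ReadCluster(GenomicInterval(chrom, cur_start, cur_end, strand), cur_count)
        )
    return clusters


def excise_precursors(
    cluster: ReadCluster,
    genome: Mapping[str, str],
    flank: int = 20,
    window_max: int = MAX_PRECURSOR_LEN,
) -> list[GenomicInterval]:
    """Flank-extended candidate window(s) for one cluster.

    A cluster wider than ``window_max`` yields one 5'-anchored and one
    3'-anchored window; windows are clipped at chromosome ends.
    """
    iv = cluster.interval
    chrom_len = len(genome[iv.chrom])
    start = max(0, iv.start - flank)
    end = min(chrom_len, iv.end + flank)
    if end - start <= window_max:
        return [GenomicInterval(iv.chrom, start, end, iv.strand)]
    return [
        GenomicInterval(iv.chrom, start, min(chrom_len, start + window_max), iv.strand),
        GenomicInterval(iv.chrom, max(0, end - window_max), end, iv.strand),
    ]


def _window_stacks(
    window: GenomicInterval, alignments_by_key: dict[tuple[str, str], list[ReadAlignment]]
) -> list[tuple[int, int, str, int]]:
    """Distinct read stacks fully inside the window: (start, end, seq, count)."""
    stacks: dict[tuple[int, str], list[int]] = {}
    for a in alignments_by_key.get((window.chrom, window.strand), ()):
        if a.start >= window.start and a.end <= window.end:
            stacks.setdefault((a.start, a.sequence), []).append(a.count)
    return [
        (start, start + len(seq), seq, sum(counts))
        for (start, seq), counts in stacks.items()
    ]


def propose_candidates(
    windows: Sequence[GenomicInterval],
    alignments: Iterable[ReadAlignment],
    genome: Mapping[str, str],
    min_len: int = MIN_PRECURSOR_LEN,
    max_len: int = MAX_PRECURSOR_LEN,
    min_cluster_count: int = 10,
    min_stem_pairs: int = 3,
    min_loop: int = 3,
) -> list[HairpinCandidate]:
    """Keep windows whose two dominant stacks flank a single stem-loop.

    The candidate is trimmed to the span of the two dominant stacks, its
    sequence folded (strand-adjusted), and accepted iff the fold is a
    single stem and the stacks sit on opposite arms of its terminal loop.
    """
    by_key: dict[tuple[str, str], list[ReadAlignment]] = {}
    for a in alignments:
        by_key.setdefault((a.target, a.strand), []).append(a)

    out: list[HairpinCandidate] = []
    seen: set[tuple[str, int, int, str]] = set()
    for window in windows:
        stacks = _window_stacks(window, by_key)
        if len(stacks) < 2 or sum(s[3] for s in stacks) < min_cluster_count:
            continue
        stacks.sort(key=lambda s: (-s[3], s[0], s[2]))
        (s1, e1, _q1, _c1), (s2, e2, _q2, _c2) = stacks[0], stacks[1]
        ext = (min(s1, s2), max(e1, e2))
        if not (min_len <= ext[1] - ext[0] <= max_len):
            continue
        locus = GenomicInterval(window.chrom, ext[0], ext[1], window.strand)
        key = (locus.chrom, locus.start, locus.end, locus.strand)
        if key in seen:
            continue
        precursor = extract_precursor(genome, locus)
        fold = nussinov_fold(precursor, min_loop)
        metrics = hairpin_metrics(fold, min_stem_pairs)
        if not metrics.single_stem or metrics.loop is None:
            continue
        # stack 5' positions in precursor coordinates
        if locus.strand == "-":
            p1, p2 = locus.end - e1, locus.end - e2
        else:
            p1, p2 = s1 - locus.start, s2 - locus.start
        loop_mid = (metrics.loop[0] + metrics.loop[1]) // 2
        lo, hi = min(p1, p2), max(p1, p2)
        if not (lo < loop_mid <= hi):
            continue
        seen.add(key)
        out.append(HairpinCandidate(locus, precursor, fold, "DISCOVERY"))
    out.sort(key=lambda c: (c.locus.chrom, c.locus.start, c.locus.end, c.locus.strand))
    return out


@dataclass
class MergedLocus:
    """Union span of overlapping candidates with their provenance."""

    interval: GenomicInterval
    members: list[HairpinCandidate] = field(default_factory=list)

    @property
    def sources(self) -> list[str]:
        return sorted({m.source for m in self.members})


def merge_candidate_sets(
    set_a: Sequence[HairpinCandidate], set_b: Sequence[HairpinCandidate]
) -> list[MergedLocus]:
    """Strand-blind union of overlapping candidate loci (idempotent).

    Merged spans keep every contributing candidate; the span's strand is
    kept only when all members agree (re-resolved downstream from the
    dominant read strand otherwise).
    """
    members = list(set_a) + list(set_b)
    merged = merge_intervals([m.locus for m in members])
    out = []
    for span in merged:
        inside = [m for m in members if m.locus.overlaps(span)]
        strands = {m.locus.strand for m in inside}
        span = span.with_strand(strands.pop() if len(strands) == 1 else ".")
        out.append(MergedLocus(span, inside))
    return out
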
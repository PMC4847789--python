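"""Simplified piRNA cluster calling.

Multimapping read counts are reallocated across their genomic placements
in proportion to the local density of uniquely mapping reads (the
reallocation idea of the proTRAC toolchain); candidate clusters are runs
of 24-32 nt read placements, accepted on span, normalized hit count, the
1T/10A sequence signature and the in-range size fraction.  The original
tool's density model and p-values are deliberately replaced by these four
explicit, config-exposed filters.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .align import ReadAlignment
from .intervals import GenomicInterval, merge_intervals

DEFAULT_SIZE_RANGE = (24, 32)


@dataclass(frozen=True)
class WeightedAlignment:
    alignment: ReadAlignment
    weight: float

    @property
    def weighted_count(self) -> float:
        return self.alignment.count * self.weight


@dataclass(frozen=True)
class PiRNACluster:
    interval: GenomicInterval
    tissue: str
    normalized_hits: float
    n_distinct_seqs: int
    frac_1t_or_10a: float
    strand_class: str  # MONO_PLUS | MONO_MINUS | DUAL


def reallocate_counts(
    alignments: Sequence[ReadAlignment], window: int = 10_000
) -> list[WeightedAlignment]:
    """Distribute each multimapper's count by local unique-mapper density.

    A read with m placements gets per-placement weights proportional to
    the summed count of uniquely mapping reads starting within +-window
    of the placement; all-zero densities fall back to a uniform 1/m
    split.  Weights of one read always sum to 1, so total count is
    conserved exactly.
    """
    by_read: dict[str, list[ReadAlignment]] = {}
    for a in alignments:
        by_read.setdefault(a.sequence, []).append(a)

    unique_pos: dict[str, list[int]] = {}
    unique_cnt: dict[str, list[int]] = {}
    for placements in by_read.values():
        if len(placements) == 1:
            a = placements[0]
            unique_pos.setdefault(a.target, []).append(a.start)
            unique_cnt.setdefault(a.target, []).append(a.count)
    prefix: dict[str, tuple[list[int], np.ndarray]] = {}
    for chrom, pos in unique_pos.items():
        order = np.argsort(pos, kind="stable")
        spos = [pos[i] for i in order]
        scnt = np.array([unique_cnt[chrom][i] for i in order], dtype=float)
        prefix[chrom] = (spos, np.concatenate([[0.0], np.cumsum(scnt)]))

    def density(chrom: str, start: int) -> float:
        entry = prefix.get(chrom)
        if entry is None:
            return 0.0
        spos, csum = entry
        lo = bisect_left(spos, start - window)
        hi = bisect_right(spos, start + window)
        return float(csum[hi] - csum[lo])

    out: list[WeightedAlignment] = []
    for seq in sorted(by_read):
        placements = sorted(by_read[seq], key=lambda a: (a.target, a.start, a.strand))
        if len(placements) == 1:
            out.append(WeightedAlignment(placements[0], 1.0))
            continue
        dens = [density(a.target, a.start) for a in placements]
        total = sum(dens)
        if total == 0:
            weights = [1.0 / len(placements)] * len(placements)
        else:
            weights = [d / total for d in dens]
        out.extend(WeightedAlignment(a, w) for a, w in zip(placements, weights))
    return out


def signature_frac(reads: Iterable[tuple[str, float]]) -> float:
    """Weighted fraction of reads with first base T *or* tenth base A.

    The two conditions count as a union; reads shorter than 10 nt are
    excluded from the denominator.
    """
    num = den = 0.0
    for seq, weight in reads:
        if len(seq) < 10:
            continue
        den += weight
        if seq[0] == "T" or seq[9] == "A":
            num += weight
    return num / den if den else 0.0


def call_clusters(
    weighted: Sequence[WeightedAlignment],
    tissue: str,
    min_size: int = 1000,
    min_hits: float = 25.0,
    min_sig: float = 0.5,
    size_range: tuple[int, int] = DEFAULT_SIZE_RANGE,
    min_size_frac: float = 0.75,
    max_gap: int = 500,
    mono_strand_share: float = 0.8,
) -> list[PiRNACluster]:
    """piRNA cluster candidates from one tissue's weighted placements."""
    in_range = [
        w for w in weighted if size_range[0] <= w.alignment.length <= size_range[1]
    ]
    if not in_range:
        return []
    spans = merge_intervals(
        [
            GenomicInterval(w.alignment.target, w.alignment.start, w.alignment.end)
            for w in in_range
        ],
        gap=max_gap,
    )
    clusters = []
    for span in spans:
        if span.length < min_size:
            continue
        inside = [
            w
            for w in weighted
            if w.alignment.target == span.chrom
            and w.alignment.start >= span.start
            and w.alignment.end <= span.end
        ]
        inside_range = [
            w for w in inside if size_range[0] <= w.alignment.length <= size_range[1]
        ]
        hits = sum(w.weighted_count for w in inside_range)
        total = sum(w.weighted_count for w in inside)
        if hits < min_hits or total == 0 or hits / total < min_size_frac:
            continue
        sig = signature_frac(
            (w.alignment.sequence, w.weighted_count) for w in inside_range
        )
        if sig < min_sig:
            continue
        plus = sum(
            w.weighted_count for w in inside_range if w.alignment.strand == "+"
        )
        share = plus / hits
        if share >= mono_strand_share:
            strand_class = "MONO_PLUS"
        elif share <= 1 - mono_strand_share:
            strand_class = "MONO_MINUS"
        else:
            strand_class = "DUAL"
        clusters.append(
            PiRNACluster(
                interval=span,
                tissue=tissue,
                normalized_hits=hits,
                n_distinct_seqs=len({w.alignment.sequence for w in inside_range}),
                frac_1t_or_10a=sig,
                strand_class=strand_class,
            )
        )
    return clusters


def merge_clusters_across_tissues(
    clusters: Sequence[PiRNACluster], mono_strand_only: bool = False
) -> list[GenomicInterval]:
    """Non-overlapping merged coordinates of the cross-tissue cluster set."""
    selected = [
        c
        for c in clusters
        if not mono_strand_only or c.strand_class in ("MONO_PLUS", "MONO_MINUS")
    ]
    return merge_intervals([c.interval for c in selected])
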
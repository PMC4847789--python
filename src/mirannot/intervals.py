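"""Genomic interval primitives and set operations.

Every coordinate in this package is 0-based, half-open, on the forward
strand of a named chromosome.  Serializers (BED, GFF3, GTF) convert at the
boundary and nowhere else.  The set operations below are strand-blind, the
semantics used throughout the annotation stages (matching coordinate-merge
behaviour of the usual BED toolchain); callers that need strand separation
partition their input first.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A located, optionally stranded feature: [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def with_strand(self, strand: str) -> "GenomicInterval":
        return replace(self, strand=strand)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"


def merge_intervals(
    intervals: Iterable[GenomicInterval], gap: int = 0
) -> list[GenomicInterval]:
    """Minimal non-overlapping cover of ``intervals`` (strand-blind).

    Intervals closer than or equal to ``gap`` (default 0: touching counts
    as overlapping, as in ``bedtools merge``) are joined.  The merged
    record keeps a strand only when every input in the run agrees.
    """
    ivs = sorted(intervals, key=lambda i: (i.chrom, i.start, i.end))
    out: list[GenomicInterval] = []
    cur: GenomicInterval | None = None
    strands: set[str] = set()
    for iv in ivs:
        if cur is not None and iv.chrom == cur.chrom and iv.start <= cur.end + gap:
            strands.add(iv.strand)
            if iv.end > cur.end:
                cur = replace(cur, end=iv.end)
        else:
            if cur is not None:
                out.append(replace(cur, strand=_common_strand(strands)))
            cur = iv
            strands = {iv.strand}
    if cur is not None:
        out.append(replace(cur, strand=_common_strand(strands)))
    return out


def _common_strand(strands: set[str]) -> str:
    return strands.pop() if len(strands) == 1 else "."


def intersect(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[tuple[GenomicInterval, GenomicInterval, GenomicInterval]]:
    """Overlap spans between the two sets, with the originating records.

    Returns one ``(span, a_record, b_record)`` triple per overlapping pair.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in sorted(b, key=lambda i: (i.chrom, i.start)):
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out = []
    for ia in sorted(a, key=lambda i: (i.chrom, i.start)):
        for ib in by_chrom.get(ia.chrom, ()):
            if ib.start >= ia.end:
                break
            if ia.overlaps(ib):
                span = GenomicInterval(
                    ia.chrom, max(ia.start, ib.start), min(ia.end, ib.end), ia.strand
                )
                out.append((span, ia, ib))
    return out


def subtract(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Parts of ``a`` not covered by any interval in ``b`` (strand-blind)."""
    cover = merge_intervals(b)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in cover:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for ia in a:
        pos = ia.start
        for ib in by_chrom.get(ia.chrom, ()):
            if ib.end <= pos or ib.start >= ia.end:
                continue
            if ib.start > pos:
                out.append(replace(ia, start=pos, end=ib.start))
            pos = max(pos, ib.end)
            if pos >= ia.end:
                break
        if pos < ia.end:
            out.append(replace(ia, start=pos, end=ia.end))
    return out
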
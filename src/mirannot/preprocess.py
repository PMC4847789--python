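"""Small RNA library preprocessing.

Adapter trimming (exact-match, leftmost occurrence of an adapter prefix of
at least ``min_overlap`` nt), the >=16 nt size filter, read collapsing,
length histograms and reads-per-million normalization.  Reads that fail
trimming are kept untrimmed; only the size filter removes reads, so the
reported tiers are "trimmed" and "trimmed >= min length".
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .io import CollapsedRead

MIN_READ_LEN = 16


@dataclass
class LibraryStats:
    """Per-library preprocessing tallies (raw -> trimmed>=16 -> genome-matching)."""

    tissue: str
    total_reads: int
    trimmed_ge_min: int
    genome_matching: int = 0
    length_histogram: dict[int, int] = field(default_factory=dict)

    def validate(self) -> "LibraryStats":
        if not self.genome_matching <= self.trimmed_ge_min <= self.total_reads:
            raise ValueError(
                f"{self.tissue}: inconsistent tiers "
                f"{self.genome_matching} <= {self.trimmed_ge_min} <= {self.total_reads}"
            )
        return self


def trim_adapter(read: str, adapter: str, min_overlap: int = 8) -> str:
    """Remove the suffix starting at the leftmost adapter match.

    A match is an exact occurrence of an adapter *prefix* of length at
    least ``min_overlap`` (shorter only when clipped by the read end is
    not accepted; a full-adapter internal occurrence always qualifies).
    Returns the read unchanged when no match is found.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if len(adapter) < min_overlap:
        raise ValueError(
            f"adapter length {len(adapter)} shorter than min_overlap {min_overlap}"
        )
    for i in range(0, len(read) - min_overlap + 1):
        m = min(len(adapter), len(read) - i)
        if m >= min_overlap and read[i : i + m] == adapter[:m]:
            return read[:i]
    return read


def collapse_reads(sequences: Iterable[str]) -> list[CollapsedRead]:
    """Collapse raw sequences to distinct reads with counts (count-conserving)."""
    counts = Counter(sequences)
    return [
        CollapsedRead(seq, n, f"read{i + 1}")
        for i, (seq, n) in enumerate(sorted(counts.items()))
    ]


def size_filter(reads: Iterable[CollapsedRead], min_len: int = MIN_READ_LEN) -> list[CollapsedRead]:
    return [r for r in reads if len(r.sequence) >= min_len]


def length_histogram(reads: Iterable[CollapsedRead]) -> dict[int, int]:
    hist: Counter[int] = Counter()
    for r in reads:
        hist[len(r.sequence)] += r.count
    return dict(sorted(hist.items()))


def rpm_normalize(count: float, genome_matching_total: int) -> float:
    """Reads per million genome-matching reads."""
    if genome_matching_total <= 0:
        raise ValueError("genome_matching_total must be positive")
    return count * 1e6 / genome_matching_total


def total_count(reads: Iterable[CollapsedRead]) -> int:
    return sum(r.count for r in reads)


def preprocess_library(
    tissue: str,
    reads: list[CollapsedRead],
    adapter: str | None = None,
    min_len: int = MIN_READ_LEN,
    min_overlap: int = 8,
) -> tuple[list[CollapsedRead], LibraryStats]:
    """Trim (optional), size-filter and re-collapse one library."""
    total = total_count(reads)
    if adapter:
        trimmed: Counter[str] = Counter()
        for r in reads:
            trimmed[trim_adapter(r.sequence, adapter, min_overlap)] += r.count
        reads = [
            CollapsedRead(seq, n, f"read{i + 1}")
            for i, (seq, n) in enumerate(sorted(trimmed.items()))
            if seq
        ]
    kept = size_filter(reads, min_len)
    stats = LibraryStats(
        tissue=tissue,
        total_reads=total,
        trimmed_ge_min=total_count(kept),
        length_histogram=length_histogram(kept),
    )
    return kept, stats
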
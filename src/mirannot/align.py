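"""Complete ungapped short-read alignment with at most one mismatch.

This is the PatMaN-role matcher of the pipeline: given collapsed reads (or
mature miRNA sequences) and one or more named target sequences, it reports
*every* position on either strand where the read matches with at most
``max_mismatch`` (0 or 1) substitutions and no gaps.  Completeness is
guaranteed by pigeonhole seeding: a query is split into ``k+1`` disjoint
segments, one of which must match exactly in any hit with <= k mismatches;
each candidate placement is then verified in full.

Reverse-strand hits are reported in forward-reference coordinates with the
strand flag set, so all downstream interval logic works in one frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .io import CollapsedRead
from .sequences import revcomp

# Targets at or below this size are scanned directly; seeding only pays
# off on chromosome-scale targets.
_BRUTE_TARGET_LEN = 2000


@dataclass(frozen=True)
class ReadAlignment:
    """One ungapped placement of a read on a target."""

    read_id: str
    target: str
    start: int  # 0-based, forward frame
    strand: str
    mismatches: int
    length: int
    count: int
    sequence: str  # read as sequenced (5'->3' of the read itself)

    @property
    def end(self) -> int:
        return self.start + self.length

    @property
    def five_prime(self) -> int:
        """Position of the read's 5' end in forward-frame coordinates."""
        return self.start if self.strand != "-" else self.end - 1


class SeedIndex:
    """Seeded exact/1-mismatch matcher over a set of named target sequences."""

    def __init__(self, targets: Mapping[str, str]):
        self.targets = dict(targets)
        self._indexes: dict[tuple[str, int], dict[str, list[int]]] = {}

    def _index(self, name: str, s: int) -> dict[str, list[int]]:
        key = (name, s)
        idx = self._indexes.get(key)
        if idx is None:
            seq = self.targets[name]
            idx = {}
            for i in range(len(seq) - s + 1):
                idx.setdefault(seq[i : i + s], []).append(i)
            self._indexes[key] = idx
        return idx

    # seed length cap: one shared index instead of one per read length;
    # disjoint segments of any common length keep the pigeonhole guarantee
    _MAX_SEED = 12

    def _candidates(self, name: str, q: str, k: int) -> Iterable[int]:
        """Candidate start positions guaranteed to include all true hits."""
        L = len(q)
        s = min(self._MAX_SEED, L // (k + 1))
        idx = self._index(name, s)
        seen: set[int] = set()
        for seg in range(k + 1):
            off = seg * s
            for pos in idx.get(q[off : off + s], ()):
                start = pos - off
                if start not in seen:
                    seen.add(start)
                    yield start

    def _find_one_strand(self, name: str, q: str, k: int) -> list[tuple[int, int]]:
        """(start, mismatches) for all hits of q on the forward target."""
        target = self.targets[name]
        L = len(q)
        if L > len(target):
            return []
        hits = []
        if len(target) <= _BRUTE_TARGET_LEN or L < 2 * (k + 1):
            starts: Iterable[int] = range(len(target) - L + 1)
        else:
            starts = sorted(self._candidates(name, q, k))
        for start in starts:
            if start < 0 or start + L > len(target):
                continue
            window = target[start : start + L]
            if k == 0:
                if window == q:
                    hits.append((start, 0))
            else:
                mm = 0
                for a, b in zip(window, q):
                    if a != b:
                        mm += 1
                        if mm > k:
                            break
                if mm <= k:
                    hits.append((start, mm))
        return hits

    def find(
        self, seq: str, max_mismatch: int = 0, strands: str = "both"
    ) -> list[tuple[str, int, str, int]]:
        """All placements of ``seq``: (target, start, strand, mismatches)."""
        if max_mismatch not in (0, 1):
            raise ValueError("max_mismatch must be 0 or 1")
        if strands not in ("both", "forward"):
            raise ValueError("strands must be 'both' or 'forward'")
        out = []
        rc = revcomp(seq) if strands == "both" else None
        for name in self.targets:
            for start, mm in self._find_one_strand(name, seq, max_mismatch):
                out.append((name, start, "+", mm))
            if rc is not None:
                for start, mm in self._find_one_strand(name, rc, max_mismatch):
                    out.append((name, start, "-", mm))
        return out

    def has_exact_match(self, seq: str) -> bool:
        for name in self.targets:
            if self._find_one_strand(name, seq, 0):
                return True
            if self._find_one_strand(name, revcomp(seq), 0):
                return True
        return False


def align_all(
    queries: Iterable[CollapsedRead],
    targets: Mapping[str, str] | SeedIndex,
    max_mismatch: int = 0,
    strands: str = "both",
) -> list[ReadAlignment]:
    """Every ungapped placement of every query, both strands by default."""
    queries = list(queries)
    if not queries:
        raise ValueError("queries must be non-empty")
    index = targets if isinstance(targets, SeedIndex) else SeedIndex(targets)
    out = []
    for q in queries:
        for target, start, strand, mm in index.find(q.sequence, max_mismatch, strands):
            out.append(
                ReadAlignment(
                    read_id=q.id,
                    target=target,
                    start=start,
                    strand=strand,
                    mismatches=mm,
                    length=len(q.sequence),
                    count=q.count,
                    sequence=q.sequence,
                )
            )
    out.sort(key=lambda a: (a.target, a.start, a.strand, a.read_id))
    return out


def genome_matching_reads(
    reads: Iterable[CollapsedRead], genome: Mapping[str, str] | SeedIndex
) -> tuple[list[CollapsedRead], int]:
    """Reads with at least one perfect genomic match, and their summed count."""
    index = genome if isinstance(genome, SeedIndex) else SeedIndex(genome)
    matching = [r for r in reads if index.has_exact_match(r.sequence)]
    return matching, sum(r.count for r in matching)
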
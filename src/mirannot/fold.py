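"""Hairpin secondary-structure prediction and stem-loop geometry checks.

Folding is base-pair maximization (Nussinov dynamic programming) over the
allowed pairs A·U, G·C and G·U with a minimum hairpin-loop size, with a
fixed deterministic traceback so dot-brackets are reproducible.  The
curation stages consume only stem/loop geometry — which positions pair,
where the terminal loop sits, how much of each arm is paired — so a
maximum-pairing structure carries all the information they need; an
external thermodynamic folder can be slotted in by constructing a
:class:`FoldResult` from its dot-bracket via :func:`fold_from_dot_bracket`
without changing any downstream contract.

Geometry note: maximum-pairing structures of genomic sequence routinely
contain one or two isolated noise pairs next to the genuine stem.  A
"stem" here therefore means a helix branch of at least ``min_stem_pairs``
(default 3) pairs; hairpin loops closed by fewer pairs are ignored when
deciding whether a structure is a single stem-loop.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass

import numpy as np

from .sequences import check_dna, normalize

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
# allowed pairs: A-T, G-C, G-T (and symmetric)
_PAIR = np.zeros((4, 4), dtype=bool)
for _a, _b in ((0, 3), (2, 1), (2, 3)):
    _PAIR[_a, _b] = _PAIR[_b, _a] = True

DEFAULT_MIN_LOOP = 3
DEFAULT_MIN_STEM_PAIRS = 3


@dataclass(frozen=True)
class FoldResult:
    """A nested secondary structure for one sequence."""

    sequence: str
    dot_bracket: str
    pairs: tuple[tuple[int, int], ...]
    min_loop: int = DEFAULT_MIN_LOOP

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class HairpinMetrics:
    """Stem-loop geometry derived from a fold."""

    single_stem: bool
    n_stem_loops: int
    loop: tuple[int, int] | None  # half-open on the sequence
    arm5: tuple[int, int] | None
    arm3: tuple[int, int] | None
    loop_len: int
    max_bulge: int
    paired_fraction_5p: float
    paired_fraction_3p: float


def _pair_matrix(seq: str) -> np.ndarray:
    codes = np.fromiter((_CODE[c] for c in seq), dtype=np.int8, count=len(seq))
    return _PAIR[codes[:, None], codes[None, :]]


def nussinov_fold(seq: str, min_loop: int = DEFAULT_MIN_LOOP) -> FoldResult:
    """Maximum base-pair nested structure with deterministic traceback.

    Tie-break order at each subproblem: pair the closing bases (i, j)
    first, then bifurcate at the smallest admissible split, then leave j
    unpaired.
    """
    seq = normalize(seq)
    check_dna(seq, "fold input")
    n = len(seq)
    if n <= min_loop + 1:
        return FoldResult(seq, "." * n, (), min_loop)

    P = _pair_matrix(seq)
    dp = np.zeros((n, n), dtype=np.int32)
    pairs_by_j = [np.flatnonzero(P[:, j]) for j in range(n)]
    for j in range(min_loop + 1, n):
        col_prev = dp[:, j - 1]
        pj = pairs_by_j[j]
        pj = pj[: np.searchsorted(pj, j - min_loop - 1, side="right")]
        for i in range(j - min_loop - 1, -1, -1):
            best = dp[i, j - 1]
            ks = pj[np.searchsorted(pj, i) :]
            if len(ks):
                left = np.where(ks > i, dp[i, np.maximum(ks - 1, 0)], 0)
                cand = left + col_prev[ks + 1] + 1
                m = int(cand.max())
                if m > best:
                    best = m
            dp[i, j] = best

    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        while j - i > min_loop:
            t = int(dp[i, j])
            if t == 0:
                break
            chosen = -1
            for k in range(i, j - min_loop):
                if not P[k, j]:
                    continue
                left = int(dp[i, k - 1]) if k > i else 0
                if left + int(dp[k + 1, j - 1]) + 1 == t:
                    chosen = k
                    break
            if chosen < 0:
                j -= 1
                continue
            pairs.append((chosen, j))
            if chosen > i:
                stack.append((i, chosen - 1))
            i, j = chosen + 1, j - 1
    pairs.sort()
    db = ["."] * n
    for a, b in pairs:
        db[a], db[b] = "(", ")"
    return FoldResult(seq, "".join(db), tuple(pairs), min_loop)


def fold_from_dot_bracket(
    seq: str, dot_bracket: str, min_loop: int = DEFAULT_MIN_LOOP
) -> FoldResult:
    """Wrap an externally produced dot-bracket as a FoldResult."""
    seq = normalize(seq)
    if len(seq) != len(dot_bracket):
        raise ValueError("sequence and dot-bracket lengths differ")
    stack: list[int] = []
    pairs = []
    for i, c in enumerate(dot_bracket):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket")
            pairs.append((stack.pop(), i))
        elif c != ".":
            raise ValueError(f"invalid dot-bracket character {c!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket")
    return FoldResult(seq, dot_bracket, tuple(sorted(pairs)), min_loop)


def hairpin_metrics(
    fold: FoldResult, min_stem_pairs: int = DEFAULT_MIN_STEM_PAIRS
) -> HairpinMetrics:
    """Stem-loop geometry: loop position, arms, bulges, paired fractions.

    ``single_stem`` is true iff exactly one hairpin loop is closed by a
    helix branch of at least ``min_stem_pairs`` pairs.
    """
    n = len(fold.sequence)
    pairs = sorted(fold.pairs)
    if not pairs:
        return HairpinMetrics(False, 0, None, None, None, 0, 0, 0.0, 0.0)

    paired_pos = sorted(p for ij in pairs for p in ij)

    def paired_in(lo: int, hi: int) -> int:  # count of paired bases in [lo, hi)
        return bisect_left(paired_pos, hi) - bisect_left(paired_pos, lo)

    innermost = [(i, j) for i, j in pairs if paired_in(i + 1, j) == 0]
    # pairs enclosing exactly one innermost loop form that loop's stem
    stems: dict[tuple[int, int], list[tuple[int, int]]] = {p: [] for p in innermost}
    for q in pairs:
        enclosed = [p for p in innermost if q[0] <= p[0] and p[1] <= q[1]]
        if len(enclosed) == 1:
            stems[enclosed[0]].append(q)
    qualifying = [p for p in innermost if len(stems[p]) >= min_stem_pairs]
    n_loops = len(qualifying)
    if n_loops == 0:
        return HairpinMetrics(False, 0, None, None, None, 0, 0, 0.0, 0.0)

    main = max(qualifying, key=lambda p: (len(stems[p]), -p[0]))
    stem = sorted(stems[main])  # outermost first
    outer = stem[0]
    loop = (main[0] + 1, main[1])
    arm5 = (outer[0], loop[0])
    arm3 = (loop[1], outer[1] + 1)
    max_bulge = 0
    for (i1, j1), (i2, j2) in zip(stem, stem[1:]):
        max_bulge = max(max_bulge, i2 - i1 - 1, j1 - j2 - 1)

    def frac(arm: tuple[int, int]) -> float:
        length = arm[1] - arm[0]
        return paired_in(*arm) / length if length else 0.0

    return HairpinMetrics(
        single_stem=n_loops == 1,
        n_stem_loops=n_loops,
        loop=loop,
        arm5=arm5,
        arm3=arm3,
        loop_len=loop[1] - loop[0],
        max_bulge=max_bulge,
        paired_fraction_5p=frac(arm5),
        paired_fraction_3p=frac(arm3),
    )


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def validate_hairpin(
    fold: FoldResult,
    mature5: tuple[int, int],
    mature3: tuple[int, int],
    min_paired: float = 0.6,
    loop_overlap_max: int = 2,
    min_stem_pairs: int = DEFAULT_MIN_STEM_PAIRS,
) -> bool:
    """Structural consistency of a mature pair with the folded hairpin.

    True iff the fold is a single stem-loop, each mature sits on its arm
    (at most ``loop_overlap_max`` nt reaching into the terminal loop), at
    least ``min_paired`` of each mature's bases are paired, and the two
    matures pair predominantly with each other.
    """
    m = hairpin_metrics(fold, min_stem_pairs)
    if not m.single_stem or m.loop is None:
        return False
    loop = m.loop
    for mat in (mature5, mature3):
        if not (0 <= mat[0] < mat[1] <= len(fold.sequence)):
            return False
    # arm placement: 5p mature before the loop, 3p after, minor loop overlap
    if mature5[0] >= loop[0] or mature5[1] > loop[1]:
        return False
    if mature3[1] <= loop[1] or mature3[0] < loop[0]:
        return False
    if _overlap(mature5, loop) > loop_overlap_max:
        return False
    if _overlap(mature3, loop) > loop_overlap_max:
        return False

    partner = {}
    for i, j in fold.pairs:
        partner[i] = j
        partner[j] = i

    def stats(mat: tuple[int, int], other: tuple[int, int]) -> tuple[float, float]:
        positions = range(mat[0], mat[1])
        paired = [p for p in positions if p in partner]
        if not paired:
            return 0.0, 0.0
        into_other = sum(1 for p in paired if other[0] <= partner[p] < other[1])
        return len(paired) / (mat[1] - mat[0]), into_other / len(paired)

    f5, x5 = stats(mature5, mature3)
    f3, x3 = stats(mature3, mature5)
    return f5 >= min_paired and f3 >= min_paired and x5 >= 0.5 and x3 >= 0.5
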
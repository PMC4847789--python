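"""Read-profile curation of hairpin loci.

Builds per-position 5'-start profiles over each precursor per tissue,
calls the 5p/3p matures from the aggregated profile, applies the
two-peak (precise Drosha/Dicer processing) test, assigns HIGH/LOW
confidence, and analyses arm dominance and switching across tissues.

Peak numerics: a "precise peak" concentrates at least ``min_fraction``
(default 0.75) of an arm's 5'-start mass within +-``window`` (default 2)
positions of the modal start, with at least ``min_count`` (default 10)
reads on the arm.  These thresholds are repository defaults exposed in
the pipeline config; the underlying processing signature itself is
qualitative.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .align import ReadAlignment
from .discovery import HairpinCandidate
from .fold import hairpin_metrics
from .preprocess import rpm_normalize

AGGREGATE = "all"


@dataclass
class ArmProfile:
    """Per-tissue read stacks on one precursor, in precursor coordinates."""

    hairpin_id: str
    tissue: str
    length: int
    stacks: dict[tuple[int, str], int] = field(default_factory=dict)  # (5' start, seq) -> count

    @property
    def total(self) -> int:
        return sum(self.stacks.values())

    @property
    def start_counts(self) -> dict[int, int]:
        out: Counter[int] = Counter()
        for (pos, _seq), c in self.stacks.items():
            out[pos] += c
        return dict(out)

    @property
    def coverage(self) -> np.ndarray:
        cov = np.zeros(self.length, dtype=np.int64)
        for (pos, seq), c in self.stacks.items():
            cov[pos : pos + len(seq)] += c
        return cov

    def add(self, pos: int, seq: str, count: int) -> None:
        key = (pos, seq)
        self.stacks[key] = self.stacks.get(key, 0) + count


@dataclass(frozen=True)
class MatureCall:
    hairpin_id: str
    arm: str  # 5p | 3p
    sequence: str
    start: int  # on precursor
    end: int
    support: int


@dataclass(frozen=True)
class TwoPeakResult:
    pass_5p: bool
    pass_3p: bool

    @property
    def overall(self) -> bool:
        return self.pass_5p and self.pass_3p


@dataclass(frozen=True)
class ConfidenceRecord:
    hairpin_id: str
    confidence: str  # HIGH | LOW
    two_peak_pass: bool
    structure_pass: bool
    both_arms_expressed: bool


def build_profiles(
    loci: Sequence[HairpinCandidate],
    alignments_by_tissue: Mapping[str, Sequence[ReadAlignment]],
) -> dict[tuple[str, str], ArmProfile]:
    """0-mismatch read stacks per locus per tissue, precursor-oriented.

    Placements fully inside the locus on its strand are projected onto
    precursor coordinates (position 0 = the hairpin's 5' end).  Because
    the precursor equals the genome substring, genome placements restricted
    to the locus are exactly the 0-mismatch hairpin alignments.
    """
    by_key: dict[tuple[str, str, str], list[ReadAlignment]] = defaultdict(list)
    for tissue, alns in alignments_by_tissue.items():
        for a in alns:
            by_key[(tissue, a.target, a.strand)].append(a)
    profiles: dict[tuple[str, str], ArmProfile] = {}
    for cand in loci:
        iv = cand.locus
        for tissue in alignments_by_tissue:
            prof = ArmProfile(cand.id, tissue, iv.length)
            for a in by_key.get((tissue, iv.chrom, iv.strand), ()):
                if a.start < iv.start or a.end > iv.end:
                    continue
                pos = (a.start - iv.start) if iv.strand != "-" else (iv.end - a.end)
                prof.add(pos, a.sequence, a.count)
            profiles[(cand.id, tissue)] = prof
    return profiles


def aggregate_profile(profiles: Iterable[ArmProfile]) -> ArmProfile:
    """Tissue-summed profile (mature calling and the two-peak test use this)."""
    profiles = list(profiles)
    agg = ArmProfile(profiles[0].hairpin_id, AGGREGATE, profiles[0].length)
    for p in profiles:
        for (pos, seq), c in p.stacks.items():
            agg.add(pos, seq, c)
    return agg


def loop_midpoint(cand: HairpinCandidate, min_stem_pairs: int = 3) -> int:
    """Arm divider: midpoint of the terminal loop (sequence midpoint fallback)."""
    m = hairpin_metrics(cand.fold, min_stem_pairs)
    if m.loop is not None:
        return (m.loop[0] + m.loop[1]) // 2
    return len(cand.precursor_seq) // 2


def split_arms(
    profile: ArmProfile, loop_mid: int
) -> dict[str, dict[tuple[int, str], int]]:
    """Assign stacks to arms by 5'-start position relative to the loop."""
    arms: dict[str, dict[tuple[int, str], int]] = {"5p": {}, "3p": {}}
    for (pos, seq), c in profile.stacks.items():
        arms["5p" if pos < loop_mid else "3p"][(pos, seq)] = c
    return arms


def call_matures(
    profile_agg: ArmProfile, loop_mid: int
) -> dict[str, MatureCall | None]:
    """Most abundant distinct read per arm; ties to earlier start, then
    lexicographic sequence.  Arms with no reads yield no call."""
    calls: dict[str, MatureCall | None] = {"5p": None, "3p": None}
    for arm, stacks in split_arms(profile_agg, loop_mid).items():
        if not stacks:
            continue
        (pos, seq), count = min(
            stacks.items(), key=lambda kv: (-kv[1], kv[0][0], kv[0][1])
        )
        calls[arm] = MatureCall(
            profile_agg.hairpin_id, arm, seq, pos, pos + len(seq), count
        )
    return calls


def two_peak_test(
    profile_agg: ArmProfile,
    loop_mid: int,
    window: int = 2,
    min_fraction: float = 0.75,
    min_count: int = 10,
) -> TwoPeakResult:
    """Precise-processing test: one dominant 5'-start peak per arm."""
    results = {}
    for arm, stacks in split_arms(profile_agg, loop_mid).items():
        starts: Counter[int] = Counter()
        for (pos, _seq), c in stacks.items():
            starts[pos] += c
        total = sum(starts.values())
        if total < min_count:
            results[arm] = False
            continue
        modal = min(starts, key=lambda p: (-starts[p], p))
        near = sum(c for p, c in starts.items() if abs(p - modal) <= window)
        results[arm] = near >= min_fraction * total
    return TwoPeakResult(results["5p"], results["3p"])


def classify_confidence(
    hairpin_id: str,
    structure_pass: bool,
    two_peak: TwoPeakResult,
    both_arms_expressed: bool,
) -> ConfidenceRecord:
    """HIGH iff processing, structure and dual-arm expression all hold."""
    high = two_peak.overall and structure_pass and both_arms_expressed
    return ConfidenceRecord(
        hairpin_id,
        "HIGH" if high else "LOW",
        two_peak.overall,
        structure_pass,
        both_arms_expressed,
    )


def arm_abundance_table(
    profiles: Mapping[tuple[str, str], ArmProfile],
    loop_mid_by_id: Mapping[str, int],
) -> pd.DataFrame:
    """Long table of per-tissue 5p/3p read counts per hairpin."""
    rows = []
    for (hid, tissue), prof in sorted(profiles.items()):
        if tissue == AGGREGATE:
            continue
        arms = split_arms(prof, loop_mid_by_id[hid])
        rows.append(
            {
                "hairpin_id": hid,
                "tissue": tissue,
                "count_5p": sum(arms["5p"].values()),
                "count_3p": sum(arms["3p"].values()),
            }
        )
    return pd.DataFrame(rows, columns=["hairpin_id", "tissue", "count_5p", "count_3p"])


def detect_arm_switching(table: pd.DataFrame, min_total: int = 20) -> list[str]:
    """Hairpins whose dominant arm differs between qualifying tissues.

    A tissue qualifies with total (5p+3p) >= ``min_total``; dominance is
    sign(5p - 3p) and exactly-balanced tissues carry no vote.
    """
    flagged = []
    for hid, sub in table.groupby("hairpin_id"):
        q = sub[(sub.count_5p + sub.count_3p) >= min_total]
        signs = set(np.sign(q.count_5p - q.count_3p)) - {0}
        if len(signs) == 2:
            flagged.append(hid)
    return sorted(flagged)


def five_prime_fraction_histogram(table: pd.DataFrame) -> pd.DataFrame:
    """Per-tissue 10-bin histogram of 5p/(5p+3p); zero-total hairpins excluded.

    Bins are [0,0.1), ..., [0.8,0.9), [0.9,1.0]."""
    edges = np.linspace(0, 1, 11)
    out = {}
    for tissue, sub in table.groupby("tissue"):
        tot = sub.count_5p + sub.count_3p
        frac = sub.count_5p[tot > 0] / tot[tot > 0]
        counts, _ = np.histogram(frac, bins=edges)
        out[tissue] = counts
    labels = [f"[{edges[i]:.1f},{edges[i + 1]:.1f})" for i in range(9)] + ["[0.9,1.0]"]
    return pd.DataFrame(out, index=labels)


def expression_matrix(
    profiles: Mapping[tuple[str, str], ArmProfile],
    genome_matching_totals: Mapping[str, int],
) -> pd.DataFrame:
    """Hairpin x tissue RPM matrix (reads per million genome-matching)."""
    hids = sorted({hid for hid, t in profiles if t != AGGREGATE})
    tissues = sorted(genome_matching_totals)
    data = {
        tissue: [
            rpm_normalize(
                profiles[(hid, tissue)].total if (hid, tissue) in profiles else 0,
                genome_matching_totals[tissue],
            )
            for hid in hids
        ]
        for tissue in tissues
    }
    return pd.DataFrame(data, index=hids)
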
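"""Profiles, mature calling, the two-peak test, confidence and arm analysis."""

import pandas as pd
import pytest

from mirannot.align import ReadAlignment
from mirannot.curation import (
    AGGREGATE,
    ArmProfile,
    aggregate_profile,
    arm_abundance_table,
    build_profiles,
    call_matures,
    classify_confidence,
    detect_arm_switching,
    five_prime_fraction_histogram,
    two_peak_test,
    TwoPeakResult,
)
from mirannot.discovery import HairpinCandidate
from mirannot.fold import nussinov_fold
from mirannot.intervals import GenomicInterval

PRE = "G" * 22 + "CAACAACAAC" + "C" * 22  # clean 22-bp stem, loop at (22, 32)
LOOP_MID = 27


def profile(stacks, hid="h", tissue=AGGREGATE, length=54):
    p = ArmProfile(hid, tissue, length)
    for (pos, seq), c in stacks.items():
        p.add(pos, seq, c)
    return p


class TestProfiles:
    def _locus(self, strand="+"):
        iv = GenomicInterval("chr1", 1000, 1000 + len(PRE), strand)
        return HairpinCandidate(iv, PRE, nussinov_fold(PRE), "DISCOVERY")

    def test_start_counts_and_conservation(self):
        cand = self._locus()
        alns = [
            ReadAlignment("a", "chr1", 1005, "+", 0, 20, 10, "X" * 20),
            ReadAlignment("b", "chr1", 1005, "+", 0, 22, 3, "Y" * 22),
            ReadAlignment("c", "chr1", 900, "+", 0, 22, 9, "Z" * 22),  # outside
        ]
        profs = build_profiles([cand], {"blood": alns})
        p = profs[(cand.id, "blood")]
        assert p.start_counts == {5: 13}
        assert p.total == 13  # outside read not counted

    def test_minus_strand_coordinates_flip(self):
        cand = self._locus("-")
        alns = [ReadAlignment("a", "chr1", 1000 + len(PRE) - 22, "-", 0, 22, 4, "Q" * 22)]
        p = build_profiles([cand], {"t": alns})[(cand.id, "t")]
        assert p.start_counts == {0: 4}

    def test_coverage_definition(self):
        p = profile({(5, "AAAAA"): 2, (7, "CCC"): 1})
        cov = p.coverage
        assert cov[5] == 2 and cov[7] == 3 and cov[9] == 3 and cov[10] == 0

    def test_aggregate_sums_tissues(self):
        a = profile({(0, "A" * 22): 5}, tissue="blood")
        b = profile({(0, "A" * 22): 7}, tissue="brain")
        agg = aggregate_profile([a, b])
        assert agg.total == 12


class TestCallMatures:
    def test_most_abundant_per_arm(self):
        p = profile({(0, "G" * 22): 50, (1, "G" * 21): 10, (32, "C" * 22): 30})
        calls = call_matures(p, LOOP_MID)
        assert calls["5p"].sequence == "G" * 22 and calls["5p"].support == 50
        assert calls["3p"].start == 32

    def test_tie_broken_by_earlier_start(self):
        p = profile({(0, "G" * 22): 10, (1, "G" * 22): 10})
        calls = call_matures(p, LOOP_MID)
        assert calls["5p"].start == 0

    def test_empty_arm_gives_no_call(self):
        p = profile({(0, "G" * 22): 10})
        calls = call_matures(p, LOOP_MID)
        assert calls["3p"] is None


class TestTwoPeak:
    def test_single_start_per_arm_passes(self):
        p = profile({(0, "G" * 22): 40, (32, "C" * 22): 40})
        assert two_peak_test(p, LOOP_MID).overall

    def test_uniform_starts_fail(self):
        stacks = {(i, f"{'G' * 21}{b}"): 2 for i in range(20) for b in "ACGT"}
        p = profile(stacks, length=80)
        assert not two_peak_test(p, 40).pass_5p

    def test_fraction_exactly_at_threshold_passes(self):
        p = profile({(0, "G" * 20): 30, (10, "G" * 12): 10, (40, "C" * 12): 40}, length=60)
        res = two_peak_test(p, 30, window=2, min_fraction=0.75, min_count=10)
        assert res.pass_5p  # 30 / 40 == 0.75 exactly

    def test_min_count_per_arm(self):
        p = profile({(0, "G" * 22): 9, (32, "C" * 22): 40})
        res = two_peak_test(p, LOOP_MID, min_count=10)
        assert not res.pass_5p and res.pass_3p

    def test_invariant_under_uniform_scaling(self):
        stacks = {(0, "G" * 22): 12, (3, "G" * 22): 3, (32, "C" * 22): 20}
        p1 = profile(stacks)
        p2 = profile({k: v * 7 for k, v in stacks.items()})
        r1, r2 = two_peak_test(p1, LOOP_MID), two_peak_test(p2, LOOP_MID)
        assert (r1.pass_5p, r1.pass_3p) == (r2.pass_5p, r2.pass_3p)


class TestConfidence:
    def test_all_criteria_high(self):
        rec = classify_confidence("h", True, TwoPeakResult(True, True), True)
        assert rec.confidence == "HIGH"

    @pytest.mark.parametrize(
        "structure,two_peak,arms",
        [
            (False, TwoPeakResult(True, True), True),
            (True, TwoPeakResult(False, True), True),
            (True, TwoPeakResult(True, True), False),
        ],
    )
    def test_any_failed_criterion_low(self, structure, two_peak, arms):
        assert classify_confidence("h", structure, two_peak, arms).confidence == "LOW"


def _arm_table(rows):
    return pd.DataFrame(rows, columns=["hairpin_id", "tissue", "count_5p", "count_3p"])


class TestArmAnalysis:
    def test_switching_flagged_on_sign_flip(self):
        table = _arm_table(
            [
                ("h1", "blood", 5, 40),
                ("h1", "brain", 50, 8),
                ("h2", "blood", 40, 5),
                ("h2", "brain", 50, 8),
            ]
        )
        assert detect_arm_switching(table) == ["h1"]

    def test_low_total_tissue_ignored(self):
        table = _arm_table([("h1", "blood", 30, 2), ("h1", "brain", 2, 10)])  # brain total 12 < 20
        assert detect_arm_switching(table, min_total=20) == []

    def test_five_prime_histogram_conserves_counts(self):
        table = _arm_table(
            [
                ("h1", "blood", 100, 0),
                ("h2", "blood", 50, 50),
                ("h3", "blood", 0, 0),  # excluded
                ("h4", "blood", 0, 30),
            ]
        )
        hist = five_prime_fraction_histogram(table)
        assert hist["blood"].sum() == 3
        assert hist["blood"].iloc[9] == 1  # all-5p in last bin
        assert hist["blood"].iloc[5] == 1  # balanced in [0.5, 0.6)
        assert hist["blood"].iloc[0] == 1

    def test_arm_abundance_from_profiles(self):
        profs = {
            ("h", "blood"): profile({(0, "G" * 22): 11, (32, "C" * 22): 4}, tissue="blood"),
        }
        table = arm_abundance_table(profs, {"h": LOOP_MID})
        row = table.iloc[0]
        assert (row.count_5p, row.count_3p) == (11, 4)
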
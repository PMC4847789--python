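"""Read-stack clustering, precursor excision and candidate proposal."""

import numpy as np
import pytest

from mirannot.align import ReadAlignment, align_all
from mirannot.discovery import (
    HairpinCandidate,
    ReadCluster,
    cluster_read_stacks,
    excise_precursors,
    merge_candidate_sets,
    propose_candidates,
)
from mirannot.fold import nussinov_fold
from mirannot.intervals import GenomicInterval
from mirannot.io import CollapsedRead
from mirannot.sequences import revcomp


def aln(start, length=22, strand="+", count=1, chrom="chr1", seq=None):
    seq = seq or "A" * length
    return ReadAlignment("r", chrom, start, strand, 0, length, count, seq)


class TestClustering:
    def test_nearby_stacks_merge(self):
        clusters = cluster_read_stacks([aln(100), aln(152)], max_gap=65)
        assert len(clusters) == 1
        assert (clusters[0].interval.start, clusters[0].interval.end) == (100, 174)
        assert clusters[0].count == 2

    def test_distant_stacks_split(self):
        clusters = cluster_read_stacks([aln(100), aln(222)], max_gap=65)
        assert len(clusters) == 2

    def test_opposite_strands_never_merge(self):
        clusters = cluster_read_stacks([aln(100, strand="+"), aln(105, strand="-")])
        assert len(clusters) == 2
        assert {c.interval.strand for c in clusters} == {"+", "-"}


class TestExcision:
    GENOME = {"chr1": "A" * 1000}

    def test_flank_extension(self):
        c = ReadCluster(GenomicInterval("chr1", 100, 180, "+"), 10)
        [w] = excise_precursors(c, self.GENOME, flank=20, window_max=300)
        assert (w.start, w.end, w.length) == (80, 200, 120)

    def test_clipped_at_chromosome_start(self):
        c = ReadCluster(GenomicInterval("chr1", 5, 60, "+"), 10)
        [w] = excise_precursors(c, self.GENOME, flank=20)
        assert w.start == 0

    def test_wide_cluster_yields_two_anchored_windows(self):
        c = ReadCluster(GenomicInterval("chr1", 100, 500, "+"), 10)
        windows = excise_precursors(c, self.GENOME, flank=20, window_max=300)
        assert len(windows) == 2
        assert windows[0].start == 80 and windows[0].length == 300
        assert windows[1].end == 520 and windows[1].length == 300


def _planted_genome(seed=0):
    """Random genome with one clean planted hairpin and its arm reads."""
    rng = np.random.default_rng(seed)
    arm5 = "GCTAGCTAGGATCGGATCGGAT"
    arm3 = revcomp(arm5)
    loop = "CAACAACCAACC"
    pre = arm5 + loop + arm3
    flanks = "".join(rng.choice(list("ACGT"), size=2000))
    genome = {"chr1": flanks[:1000] + pre + flanks[1000:]}
    reads = [CollapsedRead(arm5, 40, "m5"), CollapsedRead(arm3, 30, "m3")]
    alns = [a for a in align_all(reads, genome, 0) if a.strand == "+"]
    return genome, pre, alns


class TestProposal:
    def test_planted_hairpin_recovered(self):
        genome, pre, alns = _planted_genome()
        clusters = cluster_read_stacks(alns)
        windows = [w for c in clusters for w in excise_precursors(c, genome)]
        cands = propose_candidates(windows, alns, genome)
        assert len(cands) == 1
        cand = cands[0]
        assert (cand.locus.start, cand.locus.end) == (1000, 1000 + len(pre))
        assert cand.precursor_seq == pre

    def test_single_arm_stack_rejected(self):
        genome, _pre, alns = _planted_genome()
        arm5_only = [a for a in alns if a.start == 1000]
        clusters = cluster_read_stacks(arm5_only)
        windows = [w for c in clusters for w in excise_precursors(c, genome)]
        assert propose_candidates(windows, arm5_only, genome) == []

    def test_uniform_degradation_window_rejected(self):
        rng = np.random.default_rng(2)
        genome = {"chr1": "".join(rng.choice(list("ACGT"), size=2000))}
        alns = [
            ReadAlignment(f"b{i}", "chr1", 900 + 11 * i, "+", 0, 18, 1,
                          genome["chr1"][900 + 11 * i : 918 + 11 * i])
            for i in range(12)
        ]
        clusters = cluster_read_stacks(alns)
        windows = [w for c in clusters for w in excise_precursors(c, genome)]
        cands = propose_candidates(windows, alns, genome, min_cluster_count=10)
        assert cands == []


def _candidate(start, end, strand="+", chrom="chr1"):
    # only the interval logic is under test; precursor text is filler
    iv = GenomicInterval(chrom, start, end, strand)
    return HairpinCandidate(iv, ("ACGT" * 200)[: iv.length], nussinov_fold("GGGAAACCC"), "DISCOVERY")


class TestMergeSets:
    def test_identical_locus_collapses(self):
        a = [_candidate(100, 160)]
        b = [_candidate(100, 160)]
        merged = merge_candidate_sets(a, b)
        assert len(merged) == 1 and len(merged[0].members) == 2

    def test_disjoint_preserved(self):
        merged = merge_candidate_sets([_candidate(0, 60)], [_candidate(200, 260)])
        assert len(merged) == 2

    def test_partial_overlap_takes_union_span(self):
        merged = merge_candidate_sets([_candidate(100, 160)], [_candidate(140, 200)])
        assert len(merged) == 1
        assert (merged[0].interval.start, merged[0].interval.end) == (100, 200)

    def test_idempotent_and_commutative(self):
        a = [_candidate(0, 60), _candidate(100, 160)]
        b = [_candidate(140, 200)]
        ab = merge_candidate_sets(a, b)
        ba = merge_candidate_sets(b, a)
        assert [m.interval for m in ab] == [m.interval for m in ba]
        again = merge_candidate_sets(a + b, [])
        assert [m.interval for m in again] == [m.interval for m in ab]

    def test_strand_conflict_resolved_to_dot(self):
        merged = merge_candidate_sets(
            [_candidate(100, 160, "+")], [_candidate(140, 200, "-")]
        )
        assert merged[0].interval.strand == "."
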
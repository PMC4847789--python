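"""Multimapper reallocation, the 1T/10A signature, and cluster calling."""

import numpy as np
import pytest

from mirannot.align import ReadAlignment
from mirannot.pirna import (
    call_clusters,
    merge_clusters_across_tissues,
    PiRNACluster,
    reallocate_counts,
    signature_frac,
)
from mirannot.intervals import GenomicInterval


def aln(seq, start, count=1, chrom="c", strand="+", rid="r"):
    return ReadAlignment(rid, chrom, start, strand, 0, len(seq), count, seq)


class TestReallocation:
    def test_unique_read_keeps_full_weight(self):
        [w] = reallocate_counts([aln("T" * 26, 100)])
        assert w.weight == 1.0

    def test_proportional_to_unique_density(self):
        multi = [aln("T" * 26, 1000, count=8, rid="m"), aln("T" * 26, 50_000, count=8, rid="m")]
        uniques = [aln("A" * 26, 1100, count=30, rid="u1"), aln("G" * 26, 50_100, count=10, rid="u2")]
        weighted = reallocate_counts(multi + uniques, window=10_000)
        by_start = {w.alignment.start: w.weight for w in weighted if w.alignment.sequence == "T" * 26}
        assert by_start[1000] == pytest.approx(0.75)
        assert by_start[50_000] == pytest.approx(0.25)

    def test_zero_density_uniform_fallback(self):
        multi = [aln("T" * 26, 1000, rid="m"), aln("T" * 26, 90_000, rid="m")]
        weighted = reallocate_counts(multi)
        assert [w.weight for w in weighted] == [0.5, 0.5]

    def test_weights_sum_to_one_per_read(self):
        rng = np.random.default_rng(9)
        alns = []
        for i in range(40):
            seq = "".join(rng.choice(list("ACGT"), size=26))
            for j in range(int(rng.integers(1, 5))):
                alns.append(aln(seq, int(rng.integers(0, 200_000)), count=3, rid=f"r{i}"))
        weighted = reallocate_counts(alns)
        sums = {}
        for w in weighted:
            sums[w.alignment.sequence] = sums.get(w.alignment.sequence, 0.0) + w.weight
        assert all(abs(s - 1.0) < 1e-9 for s in sums.values())
        # total count conserved: each distinct read contributes its count once
        per_read_count = {a.sequence: a.count for a in alns}
        assert sum(w.weighted_count for w in weighted) == pytest.approx(
            sum(per_read_count.values())
        )


class TestSignature:
    def test_all_first_base_t(self):
        assert signature_frac([("T" + "A" * 25, 1.0)] * 5) == 1.0

    def test_union_not_double_counted(self):
        read_both = "T" + "A" * 8 + "A" + "G" * 16  # 1T and 10A
        assert signature_frac([(read_both, 1.0), ("G" * 26, 1.0)]) == 0.5

    def test_mixed_fraction(self):
        reads = [("T" + "G" * 25, 1.0)] * 6 + [("G" * 26, 1.0)] * 4
        assert signature_frac(reads) == pytest.approx(0.6)

    def test_short_reads_excluded_from_denominator(self):
        assert signature_frac([("TAAAA", 1.0), ("T" + "G" * 25, 1.0)]) == 1.0


def _cluster_alignments(start, end, rng, n=120, first_t=0.9, length=26, chrom="c"):
    out = []
    for i in range(n):
        pos = int(rng.integers(start, end - length))
        first = "T" if rng.random() < first_t else "G"
        seq = first + "".join(rng.choice(list("ACG"), size=length - 1))
        out.append(aln(seq, pos, rid=f"p{start}_{i}"))
    return out


class TestCallClusters:
    def test_planted_cluster_called(self):
        rng = np.random.default_rng(1)
        weighted = reallocate_counts(_cluster_alignments(10_000, 12_000, rng))
        [c] = call_clusters(weighted, "testis")
        assert c.interval.start >= 9_900 and c.interval.end <= 12_100
        assert c.frac_1t_or_10a >= 0.5 and c.strand_class == "MONO_PLUS"

    def test_small_span_rejected(self):
        rng = np.random.default_rng(2)
        weighted = reallocate_counts(_cluster_alignments(10_000, 10_800, rng))
        assert call_clusters(weighted, "t", min_size=1000) == []

    def test_weak_signature_rejected(self):
        rng = np.random.default_rng(3)
        weighted = reallocate_counts(_cluster_alignments(10_000, 12_000, rng, first_t=0.25))
        assert call_clusters(weighted, "t", min_sig=0.5) == []

    def test_low_hits_rejected(self):
        rng = np.random.default_rng(4)
        weighted = reallocate_counts(_cluster_alignments(10_000, 12_000, rng, n=15))
        assert call_clusters(weighted, "t", min_hits=25) == []

    def test_out_of_range_reads_break_size_fraction(self):
        rng = np.random.default_rng(5)
        good = _cluster_alignments(10_000, 12_000, rng, n=40)
        short = _cluster_alignments(10_000, 12_000, rng, n=120, length=18)
        weighted = reallocate_counts(good + short)
        assert call_clusters(weighted, "t", min_size_frac=0.75) == []


class TestMerge:
    def _cluster(self, start, end, tissue, strand_class="MONO_PLUS"):
        return PiRNACluster(GenomicInterval("c", start, end), tissue, 100.0, 50, 0.8, strand_class)

    def test_same_cluster_across_tissues_merges(self):
        clusters = [self._cluster(0, 2000, t) for t in ("testis", "ovary", "brain")]
        assert merge_clusters_across_tissues(clusters) == [GenomicInterval("c", 0, 2000)]

    def test_disjoint_preserved_and_nonoverlapping(self):
        clusters = [self._cluster(0, 2000, "a"), self._cluster(5000, 7500, "b")]
        merged = merge_clusters_across_tissues(clusters)
        assert len(merged) == 2
        assert merged == merge_clusters_across_tissues(
            [self._cluster(m.start, m.end, "x") for m in merged]
        )

    def test_mono_strand_filter(self):
        clusters = [self._cluster(0, 2000, "a", "DUAL"), self._cluster(5000, 7000, "b")]
        assert len(merge_clusters_across_tissues(clusters, mono_strand_only=True)) == 1
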
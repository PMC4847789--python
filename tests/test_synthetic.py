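"""The synthetic study generator: genome, planting, read simulation, truth."""

import math

import numpy as np
import pytest

from mirannot.intervals import GenomicInterval
from mirannot.preprocess import length_histogram
from mirannot.sequences import revcomp
from mirannot.synthetic import (
    PlacementError,
    PlantSpec,
    PlantedHairpin,
    TruthTable,
    build_demo_truth,
    expected_counts,
    make_genome,
    plant_hairpin,
    read_truth,
    simulate_reads,
    write_truth,
)


class TestMakeGenome:
    def test_deterministic_for_seed(self):
        assert make_genome(1, 10_000, 0.5, 7) == make_genome(1, 10_000, 0.5, 7)

    def test_alphabet_and_naming(self):
        genome = make_genome(2, 10_000, 0.5, 1)
        assert set(genome) == {"chr1", "chr2"}
        assert set(genome["chr1"]) <= set("ACGT")

    def test_gc_zero_gives_at_only(self):
        genome = make_genome(1, 10_000, 0.0, 3)
        assert set(genome["chr1"]) <= {"A", "T"}

    def test_different_seeds_differ(self):
        assert make_genome(1, 10_000, 0.5, 1) != make_genome(1, 10_000, 0.5, 2)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            make_genome(0, 10_000, 0.5, 1)
        with pytest.raises(ValueError):
            make_genome(1, 500, 0.5, 1)


def toy_spec(**kw):
    defaults = dict(
        id="T1",
        context="INTERGENIC",
        arm5_seq="G" * 21,
        arm3_seq="C" * 21,
        loop_seq="CAAAAAAA",
        strand="+",
        tissue_expression={"blood": 1000},
        arm5_fraction={"blood": 1.0},
    )
    defaults.update(kw)
    return PlantSpec(**defaults)


class TestPlantHairpin:
    def test_construction_on_plus_strand(self):
        genome = make_genome(1, 10_000, 0.5, 1)
        truth = TruthTable()
        iv = plant_hairpin(genome, toy_spec(), "chr1", 5000, truth)
        assert genome["chr1"][5000:5050] == "G" * 21 + "CAAAAAAA" + "C" * 21
        assert iv == GenomicInterval("chr1", 5000, 5050, "+")

    def test_minus_strand_writes_reverse_complement(self):
        genome = make_genome(1, 10_000, 0.5, 1)
        spec = toy_spec(strand="-")
        plant_hairpin(genome, spec, "chr1", 5000, TruthTable())
        assert genome["chr1"][5000:5050] == revcomp(spec.precursor)

    def test_overlap_rejected(self):
        genome = make_genome(1, 10_000, 0.5, 1)
        truth = TruthTable()
        plant_hairpin(genome, toy_spec(), "chr1", 5000, truth)
        with pytest.raises(PlacementError):
            plant_hairpin(genome, toy_spec(id="T2"), "chr1", 5020, truth)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            toy_spec(arm3_seq="A" * 21)  # arms cannot pair
        with pytest.raises(ValueError):
            toy_spec(nta_fractions={"A": 0.6, "U": 0.5})

    def test_demo_mirtron_plants_coincide_with_short_introns(self):
        _genome, truth = build_demo_truth(seed=7)
        introns = {
            (i.chrom, i.start, i.end)
            for m in truth.gene_models
            for a, b in zip(m.exons, m.exons[1:])
            for i in [GenomicInterval(m.chrom, a.end, b.start)]
        }
        mirtrons = [p for p in truth.plants if p.spec.context == "MIRTRON"]
        assert len(mirtrons) == 3
        for p in mirtrons:
            assert 50 <= p.interval.length <= 120
            assert (p.interval.chrom, p.interval.start, p.interval.end) in introns


@pytest.fixture(scope="module")
def demo():
    return build_demo_truth(seed=11)


class TestSimulateReads:

    def test_unknown_tissue_rejected(self, demo):
        genome, truth = demo
        with pytest.raises(ValueError):
            simulate_reads(truth, genome, "spleen")

    def test_deterministic(self, demo):
        genome, truth = demo
        a = simulate_reads(truth, genome, "blood", seed=5)
        b = simulate_reads(truth, genome, "blood", seed=5)
        assert a == b

    def test_zero_expression_plant_emits_no_reads(self):
        genome = make_genome(1, 10_000, 0.5, 1)
        truth = TruthTable()
        spec = toy_spec(tissue_expression={})
        plant_hairpin(genome, spec, "chr1", 5000, truth)
        reads = simulate_reads(truth, genome, "blood", background_fraction=0.0)
        assert reads == []

    def test_nta_counts_within_three_sigma(self):
        genome = make_genome(1, 20_000, 0.5, 2)
        truth = TruthTable()
        spec = toy_spec(
            arm5_seq="GATCGATCGGATCGGATCGGA",
            arm3_seq=revcomp("GATCGATCGGATCGGATCGGA"),
            tissue_expression={"blood": 1000},
            arm5_fraction={"blood": 1.0},
            nta_fractions={"U": 0.5},
        )
        plant_hairpin(genome, spec, "chr1", 5000, truth)
        reads = simulate_reads(truth, genome, "blood", seed=3, background_fraction=0.0)
        plus_u = sum(r.count for r in reads if r.sequence == spec.arm5_seq + "T")
        sigma = math.sqrt(1000 * 0.5 * 0.5)
        assert abs(plus_u - 500) <= 3 * sigma

    def test_library_mode_is_22(self, demo):
        genome, truth = demo
        hist = length_histogram(simulate_reads(truth, genome, "blood", seed=1))
        assert max(hist, key=hist.get) == 22

    def test_total_count_matches_expectations(self, demo):
        genome, truth = demo
        tissue = "brain"
        reads = simulate_reads(truth, genome, tissue, seed=2, background_fraction=0.0)
        total = sum(r.count for r in reads)
        expected = sum(expected_counts(p, tissue)[0] for p in truth.plants)
        expected += sum(
            round(c.tissue_expression.get(tissue, 0)) for c in truth.pirna_clusters
        )
        # reads can only be lost at chromosome edges (none in the demo layout)
        assert total == expected


class TestTruthRoundTrip:
    def test_write_then_read_identity(self, tmp_path):
        _genome, truth = build_demo_truth(seed=5)
        write_truth(truth, tmp_path)
        assert read_truth(tmp_path) == truth

    def test_empty_truth_round_trips(self, tmp_path):
        truth = TruthTable()
        write_truth(truth, tmp_path)
        assert read_truth(tmp_path) == truth

    def test_mirtron_flag_in_gff3(self, tmp_path):
        _genome, truth = build_demo_truth(seed=5)
        write_truth(truth, tmp_path)
        text = (tmp_path / "truth.gff3").read_text()
        assert text.count("mirtron=true") == 3
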
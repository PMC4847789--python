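"""Homology mapping, mature confirmation, known/novel partitioning."""

import numpy as np
import pytest

from mirannot.homology import (
    HomologyHit,
    confirm_mature,
    find_cross_species_homologs,
    map_hairpins,
    split_known_novel,
)
from mirannot.intervals import GenomicInterval
from mirannot.sequences import revcomp


def rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture()
def rng():
    return np.random.default_rng(23)


class TestMapHairpins:
    def test_exact_copy_found_with_full_identity(self, rng):
        query = rand_seq(rng, 70)
        genome = {"c": rand_seq(rng, 3000) + query + rand_seq(rng, 3000)}
        hits = map_hairpins({"q": query}, genome)
        exact = [h for h in hits if h.identity == 1.0]
        assert len(exact) == 1
        h = exact[0]
        assert (h.locus.start, h.locus.end, h.locus.strand, h.alignment_length) == (3000, 3070, "+", 70)

    def test_reverse_strand_copy_found(self, rng):
        query = rand_seq(rng, 70)
        genome = {"c": rand_seq(rng, 1000) + revcomp(query) + rand_seq(rng, 1000)}
        hits = map_hairpins({"q": query}, genome)
        assert any(h.locus.strand == "-" and h.identity == 1.0 for h in hits)

    def test_59nt_partial_copy_not_retained(self, rng):
        query = rand_seq(rng, 48) + "A" * 22  # tail that cannot re-match the flank
        partial = query[:59]
        genome = {"c": rand_seq(rng, 1000) + partial + "C" * 30 + rand_seq(rng, 1000)}
        hits = map_hairpins({"q": query}, genome, min_len=60)
        assert hits == []

    def test_diverged_copy_dropped_at_identity_threshold(self, rng):
        query = rand_seq(rng, 80)
        diverged = list(query)
        for p in range(0, 80, 4):  # 25% divergence, evenly spread
            diverged[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[diverged[p]]
        genome = {"c": rand_seq(rng, 500) + "".join(diverged) + rand_seq(rng, 500)}
        hits = map_hairpins({"q": query}, genome, min_len=60, min_identity=0.8)
        assert all(h.identity >= 0.8 and h.alignment_length >= 60 for h in hits)
        assert not any(h.locus.start <= 540 <= h.locus.end and h.alignment_length >= 60 for h in hits)

    def test_short_query_rejected(self):
        with pytest.raises(ValueError):
            map_hairpins({"q": "ACGT" * 10}, {"c": "A" * 200}, min_len=60)

    def test_every_planted_copy_found(self, rng):
        queries = {f"q{i}": rand_seq(rng, 64) for i in range(5)}
        chrom = rand_seq(rng, 500)
        positions = {}
        for i, (qid, q) in enumerate(queries.items()):
            positions[qid] = len(chrom)
            chrom += q + rand_seq(rng, 300)
        hits = map_hairpins(queries, {"c": chrom})
        for qid, pos in positions.items():
            assert any(
                h.query_id == qid and h.locus.start == pos and h.identity == 1.0
                for h in hits
            )


class TestConfirmMature:
    def _hit(self, genome):
        return HomologyHit("q", GenomicInterval("c", 100, 170, "+"), 70, 1.0)

    def test_exact_mature_confirms_with_zero_mismatches(self, rng):
        genome = {"c": rand_seq(rng, 300)}
        mature = genome["c"][110:132]
        hit = confirm_mature(self._hit(genome), [mature], genome)
        assert hit.mature_confirmed and hit.mature_mismatches == 0

    def test_two_mismatches_not_confirmed(self, rng):
        genome = {"c": rand_seq(rng, 300)}
        mature = list(genome["c"][110:132])
        mature[3] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mature[3]]
        mature[10] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mature[10]]
        hit = confirm_mature(self._hit(genome), ["".join(mature)], genome)
        assert not hit.mature_confirmed

    def test_mature_overlapping_locus_edge_not_confirmed(self, rng):
        genome = {"c": rand_seq(rng, 300)}
        mature = genome["c"][160:182]  # extends past locus end at 170
        hit = confirm_mature(self._hit(genome), [mature], genome)
        assert not hit.mature_confirmed


class TestSplitKnownNovel:
    CONS = [GenomicInterval("c", 100, 170)]
    EXISTING = [GenomicInterval("c", 90, 180)]

    def test_candidate_on_conserved_locus(self):
        res = split_known_novel([GenomicInterval("c", 100, 170)], self.CONS, self.EXISTING)
        assert res["conserved"] and not res["novel"]

    def test_disjoint_candidate_is_novel(self):
        res = split_known_novel([GenomicInterval("c", 500, 560)], self.CONS, self.EXISTING)
        assert res["novel"] and not res["conserved"]

    def test_newly_annotated_when_absent_from_existing(self):
        res = split_known_novel([], [GenomicInterval("c", 100, 170), GenomicInterval("c", 400, 460)], self.EXISTING)
        assert res["newly_annotated"] == [GenomicInterval("c", 400, 460)]

    def test_partition_property(self):
        cands = [GenomicInterval("c", s, s + 60) for s in range(0, 1000, 90)]
        res = split_known_novel(cands, self.CONS, self.EXISTING)
        assert sorted(res["conserved"] + res["novel"]) == sorted(cands)
        assert not (set(res["conserved"]) & set(res["novel"]))


class TestCrossSpecies:
    def test_planted_intronic_homolog_recovered(self, rng):
        hairpin = rand_seq(rng, 64)
        other = {"s2": rand_seq(rng, 2000) + hairpin + rand_seq(rng, 2000)}
        features = {"INTRON": [(GenomicInterval("s2", 1950, 2150), "tx1")]}
        mature = hairpin[:22]
        table = find_cross_species_homologs(
            {"novel1": hairpin}, other, features, {"novel1": [mature]}, {"novel1": "INTRON"}
        )
        assert len(table) == 1
        row = table.iloc[0]
        assert (row.source_context, row.target_context) == ("INTRON", "INTRON")
        assert row.start == 2000 and row.mature_mismatches == 0

    def test_mature_two_mismatches_excluded(self, rng):
        hairpin = rand_seq(rng, 64)
        other = {"s2": rand_seq(rng, 500) + hairpin + rand_seq(rng, 500)}
        bad_mature = list(hairpin[:22])
        bad_mature[2] = {"A": "C", "C": "A", "G": "T", "T": "G"}[bad_mature[2]]
        bad_mature[8] = {"A": "C", "C": "A", "G": "T", "T": "G"}[bad_mature[8]]
        table = find_cross_species_homologs(
            {"n": hairpin}, other, {}, {"n": ["".join(bad_mature)]}, {"n": "INTRON"}
        )
        assert table.empty

    def test_no_hit_genome_gives_empty_table(self, rng):
        table = find_cross_species_homologs(
            {"n": rand_seq(rng, 64)}, {"s2": rand_seq(rng, 5000)}, {}, {"n": []}, {}
        )
        assert table.empty
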
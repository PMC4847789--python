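"""Evaluation of a pipeline run against a planted truth table.

Used to validate the pipeline on synthetic studies: planted-locus
recall/precision, miRtron recovery, piRNA cluster tissue specificity,
arm-switching exactness and non-templated-addition fraction recovery
(as binomial z-scores against the planted fractions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .intervals import GenomicInterval
from .pipeline import Pipeline
from .synthetic import TruthTable, expected_counts

MIN_RECALL_COUNT = 50  # plants below this total read count are not expected back


@dataclass
class RunEvaluation:
    recall: float
    precision: float
    n_expected: int
    n_reported: int
    matched_by_plant: dict[str, list[str]] = field(default_factory=dict)
    plant_by_locus: dict[str, str] = field(default_factory=dict)
    mirtron_calls: list[str] = field(default_factory=list)  # plant ids
    mirtron_coverages: list[float] = field(default_factory=list)
    mirtron_lengths: list[int] = field(default_factory=list)
    pirna_by_tissue: dict[str, int] = field(default_factory=dict)
    switching_flagged: set[str] = field(default_factory=set)  # plant ids
    switching_expected: set[str] = field(default_factory=set)
    nta_z: dict[tuple[str, str, str], float] = field(default_factory=dict)

    @property
    def switching_exact(self) -> bool:
        return self.switching_flagged == self.switching_expected

    @property
    def max_abs_nta_z(self) -> float:
        return max((abs(z) for z in self.nta_z.values()), default=0.0)


def _match_loci(truth: TruthTable, loci: pd.DataFrame):
    by_plant: dict[str, list[str]] = {}
    plant_of: dict[str, str] = {}
    for row in loci.itertuples():
        iv = GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand)
        for p in truth.plants:
            if iv.overlaps(p.interval):
                by_plant.setdefault(p.spec.id, []).append(row.hairpin_id)
                plant_of[row.hairpin_id] = p.spec.id
                break
    return by_plant, plant_of


def expected_switching(truth: TruthTable, min_total: int = 20) -> set[str]:
    """Plants generated with opposite per-tissue dominant arms."""
    out = set()
    for p in truth.plants:
        signs = set()
        for tissue, frac in p.spec.arm5_fraction.items():
            total = expected_counts(p, tissue)[0]
            if total >= min_total and frac != 0.5:
                signs.add(1 if frac > 0.5 else -1)
        if len(signs) == 2:
            out.add(p.spec.id)
    return out


def evaluate_run(truth: TruthTable, pipeline: Pipeline) -> RunEvaluation:
    loci = pipeline.final_loci()
    by_plant, plant_of = _match_loci(truth, loci)

    expected = [
        p
        for p in truth.plants
        if sum(expected_counts(p, t)[0] for t in truth.tissues) >= MIN_RECALL_COUNT
    ]
    recalled = sum(1 for p in expected if p.spec.id in by_plant)
    n_reported = len(loci)
    n_true = sum(1 for hid in loci.hairpin_id if hid in plant_of)

    ev = RunEvaluation(
        recall=recalled / len(expected) if expected else 1.0,
        precision=n_true / n_reported if n_reported else 1.0,
        n_expected=len(expected),
        n_reported=n_reported,
        matched_by_plant=by_plant,
        plant_by_locus=plant_of,
    )

    mirtrons = pd.read_csv(pipeline.path("mirtrons.tsv"), sep="\t")
    for row in mirtrons.itertuples():
        ev.mirtron_calls.append(plant_of.get(row.hairpin_id, row.hairpin_id))
        ev.mirtron_coverages.append(float(row.intron_coverage))
        ev.mirtron_lengths.append(int(row.intron_length))

    clusters = pd.read_csv(pipeline.path("pirna_clusters.tsv"), sep="\t")
    ev.pirna_by_tissue = {
        t: int((clusters.tissue == t).sum()) for t in truth.tissues
    }

    switching = pd.read_csv(pipeline.path("switching.tsv"), sep="\t")
    ev.switching_flagged = {
        plant_of.get(h, h) for h in switching.hairpin_id.tolist()
    }
    ev.switching_expected = expected_switching(
        truth, pipeline.config.switching_min_total
    )

    iso = pd.read_csv(pipeline.path("isomir_counts.tsv"), sep="\t")
    for p in truth.plants:
        if not p.spec.nta_fractions or p.spec.id not in by_plant:
            continue
        hid = by_plant[p.spec.id][0]
        sub = iso[iso.mature_id == f"{hid}-5p"].set_index("tissue")
        for tissue in sorted(p.spec.tissue_expression):
            _n, n5, _n3 = expected_counts(p, tissue)
            for base, col in (("A", "PLUS_A"), ("U", "PLUS_U")):
                frac = p.spec.nta_fractions.get(base, 0.0)
                if frac == 0 or n5 == 0:
                    continue
                obs = int(sub.loc[tissue, col]) if tissue in sub.index else 0
                sigma = math.sqrt(n5 * frac * (1 - frac))
                ev.nta_z[(p.spec.id, tissue, base)] = (obs - n5 * frac) / sigma
    return ev
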
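"""Synthetic small-RNA study generator with planted ground truth.

Emulates the structure of a multi-tissue small RNA-seq annotation study:
a random genome with gene models, planted miRNA stem-loops in defined
genomic contexts (intron, exon, UTR, intergenic, and splicing-defined
miRtrons whose precursor *is* a short intron), per-tissue read libraries
with Dicer/Drosha-like two-peak stacks, non-templated 3' A/U isomiRs at
controlled fractions, uniform degradation background, and testis-
restricted piRNA clusters of 24-30 nt reads with a first-base-T bias.

Generative model notes (the package's own choices, since only the
qualitative data structure is prescribed by the emulated study design):

* Read 5' starts sit at the arm's modal position; with probability
  ``jitter_prob`` a read shifts by a uniform magnitude 1-8 nt (sign
  uniform).  Read length is the arm length plus {-1, 0, +1} with weights
  0.2/0.6/0.2.  At the default jitter of 0.2 an arm's 5'-start mass is
  ~92% within +-2 nt of the mode (a "precise peak"); at jitter 0.6 it
  drops to ~71%, below the curation threshold — sloppily processed loci.
* Hairpin loops are drawn from {A, C} only and start with C: A and C
  cannot pair under the A·U/G·C/G·U rule, so the planted stem folds into
  a single stem-loop deterministically, and the base templated 3' of the
  5p mature is never A or T, so planted +A/+U additions are non-templated
  by construction.
* Non-templated additions apply to 5p-arm reads: an affected read is the
  exact 5p mature plus one 3' A or T (no jitter), drawn per read.
* piRNA first-base bias is produced by sampling read *positions* whose
  genomic first base is T (probability = the cluster's bias), so every
  simulated read remains a perfect genomic substring.
* Background degradation: 5% of each library, uniform genomic positions
  and strands, lengths uniform 16-30.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from collections import Counter
from pathlib import Path
from typing import Mapping

import numpy as np

from .intervals import GenomicInterval
from .io import (
    CollapsedRead,
    GeneModel,
    to_gff3,
    write_collapsed,
    write_fasta,
)
from .sequences import revcomp

TISSUES = (
    "blood",
    "brain",
    "heart",
    "kidney",
    "lung",
    "ovary",
    "skin",
    "smooth_muscle",
    "testis",
)

CONTEXTS = ("INTRON", "EXON", "UTR", "INTERGENIC", "MIRTRON")

_PARTNERS = {"A": {"T"}, "C": {"G"}, "G": {"C", "T"}, "T": {"A", "G"}}

DEFAULT_JITTER_PROB = 0.2
JITTER_MAX_SHIFT = 8
LEN_DELTAS = (-1, 0, 1)
LEN_WEIGHTS = (0.2, 0.6, 0.2)
BACKGROUND_FRACTION = 0.05


class PlacementError(ValueError):
    """Requested plant position collides with an existing feature."""


def _pairs(a: str, b: str) -> bool:
    return b in _PARTNERS[a]


@dataclass
class PlantSpec:
    """Blueprint of one planted miRNA stem-loop."""

    id: str
    context: str
    arm5_seq: str
    arm3_seq: str
    loop_seq: str
    strand: str = "+"
    tissue_expression: dict[str, int] = field(default_factory=dict)
    arm5_fraction: dict[str, float] = field(default_factory=dict)  # per tissue
    nta_fractions: dict[str, float] = field(default_factory=dict)  # {"A": p, "U": p}
    jitter_prob: float = DEFAULT_JITTER_PROB
    conserved: bool = False
    in_existing_annotation: bool = False

    def __post_init__(self) -> None:
        if self.context not in CONTEXTS:
            raise ValueError(f"{self.id}: unknown context {self.context}")
        if sum(self.nta_fractions.values()) >= 1:
            raise ValueError(f"{self.id}: NTA fractions must sum to < 1")
        if set(self.nta_fractions) - {"A", "U"}:
            raise ValueError(f"{self.id}: NTA bases must be A or U")
        if len(self.arm3_seq) != len(self.arm5_seq):
            raise ValueError(f"{self.id}: arm lengths differ")
        L = len(self.arm5_seq)
        pairing = sum(
            1 for i in range(L) if _pairs(self.arm5_seq[L - 1 - i], self.arm3_seq[i])
        )
        if pairing < len(self.arm5_seq) - 3:
            raise ValueError(
                f"{self.id}: arms pair at only {pairing}/{len(self.arm5_seq)} positions"
            )

    @property
    def precursor(self) -> str:
        return self.arm5_seq + self.loop_seq + self.arm3_seq

    def fraction_5p(self, tissue: str) -> float:
        return self.arm5_fraction.get(tissue, 0.5)


@dataclass
class PlantedHairpin:
    """A PlantSpec realized at a genomic interval."""

    spec: PlantSpec
    interval: GenomicInterval

    def arm5_five_prime(self) -> int:
        """Genomic position of the 5p arm's 5' end."""
        iv = self.interval
        return iv.start if iv.strand != "-" else iv.end - 1

    def arm3_five_prime(self) -> int:
        iv = self.interval
        L3 = len(self.spec.arm3_seq)
        return iv.end - L3 if iv.strand != "-" else iv.start + L3 - 1

    def mature5_interval(self) -> GenomicInterval:
        iv = self.interval
        L = len(self.spec.arm5_seq)
        if iv.strand == "-":
            return GenomicInterval(iv.chrom, iv.end - L, iv.end, "-")
        return GenomicInterval(iv.chrom, iv.start, iv.start + L, "+")


@dataclass
class PiRNAClusterSpec:
    """A planted piRNA-producing genomic window."""

    id: str
    interval: GenomicInterval
    bias_1t: float = 0.8
    tissue_expression: dict[str, int] = field(default_factory=dict)
    length_range: tuple[int, int] = (24, 30)


@dataclass
class TruthTable:
    """Everything planted: hairpins, piRNA clusters, gene models."""

    plants: list[PlantedHairpin] = field(default_factory=list)
    pirna_clusters: list[PiRNAClusterSpec] = field(default_factory=list)
    gene_models: list[GeneModel] = field(default_factory=list)
    tissues: tuple[str, ...] = TISSUES

    def plant_by_id(self, pid: str) -> PlantedHairpin:
        return next(p for p in self.plants if p.spec.id == pid)


# ---------------------------------------------------------------------------
# Genome construction


def make_genome(
    n_chrom: int, length_per_chrom: int, gc: float, seed: int
) -> dict[str, str]:
    """Random chromosomes over {A,C,G,T} at the given GC content."""
    if n_chrom <= 0 or length_per_chrom <= 0:
        raise ValueError("n_chrom and length_per_chrom must be positive")
    if length_per_chrom < 10_000:
        raise ValueError("length_per_chrom must be >= 10000")
    if not (0 <= gc <= 1):
        raise ValueError("gc must be within [0, 1]")
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    alphabet = np.array(list("ACGT"))
    return {
        f"chr{i + 1}": "".join(rng.choice(alphabet, size=length_per_chrom, p=p))
        for i in range(n_chrom)
    }


def plant_hairpin(
    genome: dict[str, str],
    spec: PlantSpec,
    chrom: str,
    position: int,
    truth: TruthTable,
) -> GenomicInterval:
    """Write the precursor into the genome and record it in the truth table.

    On the minus strand the written genomic sequence is the reverse
    complement, so the transcript-orientation substring equals the
    precursor.  Overlap with a previously planted hairpin is an error.
    """
    seq = spec.precursor
    chrom_seq = genome[chrom]
    if position < 0 or position + len(seq) > len(chrom_seq):
        raise PlacementError(f"{spec.id}: no room at {chrom}:{position}")
    interval = GenomicInterval(chrom, position, position + len(seq), spec.strand)
    for other in truth.plants:
        if other.interval.overlaps(interval):
            raise PlacementError(f"{spec.id}: overlaps {other.spec.id}")
    written = revcomp(seq) if spec.strand == "-" else seq
    genome[chrom] = chrom_seq[:position] + written + chrom_seq[position + len(seq):]
    planted = PlantedHairpin(spec, interval)
    truth.plants.append(planted)
    return interval


def _read_from(genome: Mapping[str, str], chrom: str, p5: int, length: int, strand: str) -> str | None:
    """Templated read starting at 5' genomic position p5, strand-adjusted."""
    seq = genome[chrom]
    if strand == "-":
        lo, hi = p5 - length + 1, p5 + 1
    else:
        lo, hi = p5, p5 + length
    if lo < 0 or hi > len(seq):
        return None
    sub = seq[lo:hi]
    return revcomp(sub) if strand == "-" else sub


# ---------------------------------------------------------------------------
# Read simulation


def expected_counts(
    plant: PlantedHairpin, tissue: str, depth_scale: float = 1.0
) -> tuple[int, int, int]:
    """Deterministic (total, 5p-arm, 3p-arm) read counts for one tissue."""
    n = round(plant.spec.tissue_expression.get(tissue, 0) * depth_scale)
    n5 = round(n * plant.spec.fraction_5p(tissue))
    return n, n5, n - n5


def _arm_reads(
    rng: np.random.Generator,
    genome: Mapping[str, str],
    chrom: str,
    p5_modal: int,
    arm_len: int,
    strand: str,
    n: int,
    jitter_prob: float,
    counter: Counter,
) -> None:
    if n <= 0:
        return
    jittered = rng.random(n) < jitter_prob
    mags = rng.integers(1, JITTER_MAX_SHIFT + 1, size=n)
    signs = rng.choice([-1, 1], size=n)
    shifts = np.where(jittered, mags * signs, 0)
    lengths = arm_len + rng.choice(LEN_DELTAS, size=n, p=LEN_WEIGHTS)
    direction = -1 if strand == "-" else 1
    for shift, length in zip(shifts, lengths):
        seq = _read_from(genome, chrom, p5_modal + direction * int(shift), int(length), strand)
        if seq is not None:
            counter[seq] += 1


def simulate_reads(
    truth: TruthTable,
    genome: Mapping[str, str],
    tissue: str,
    depth_scale: float = 1.0,
    seed: int = 0,
    background_fraction: float = BACKGROUND_FRACTION,
) -> list[CollapsedRead]:
    """One tissue library as collapsed reads, deterministic for a seed."""
    if tissue not in truth.tissues:
        raise ValueError(f"unknown tissue {tissue!r}; expected one of {truth.tissues}")
    rng = np.random.default_rng([seed, list(truth.tissues).index(tissue)])
    counter: Counter[str] = Counter()
    n_signal = 0
    for plant in truth.plants:
        spec = plant.spec
        n, n5, n3 = expected_counts(plant, tissue, depth_scale)
        if n == 0:
            continue
        n_signal += n
        p_a = spec.nta_fractions.get("A", 0.0)
        p_u = spec.nta_fractions.get("U", 0.0)
        n_a, n_u, n_canon = (
            rng.multinomial(n5, [p_a, p_u, 1 - p_a - p_u]) if n5 else (0, 0, 0)
        )
        mature5 = spec.arm5_seq
        if n_a:
            counter[mature5 + "A"] += int(n_a)
        if n_u:
            counter[mature5 + "T"] += int(n_u)
        _arm_reads(
            rng, genome, plant.interval.chrom, plant.arm5_five_prime(),
            len(spec.arm5_seq), spec.strand, int(n_canon), spec.jitter_prob, counter,
        )
        _arm_reads(
            rng, genome, plant.interval.chrom, plant.arm3_five_prime(),
            len(spec.arm3_seq), spec.strand, n3, spec.jitter_prob, counter,
        )
    for cluster in truth.pirna_clusters:
        n = round(cluster.tissue_expression.get(tissue, 0) * depth_scale)
        if n == 0:
            continue
        n_signal += n
        iv = cluster.interval
        chrom_seq = genome[iv.chrom]
        lo_len, hi_len = cluster.length_range
        if iv.strand == "-":
            anchor_positions = [
                p for p in range(iv.start + lo_len - 1, iv.end) if chrom_seq[p] == "A"
            ]
        else:
            anchor_positions = [
                p for p in range(iv.start, iv.end - lo_len + 1) if chrom_seq[p] == "T"
            ]
        for _ in range(n):
            length = int(rng.integers(lo_len, hi_len + 1))
            if anchor_positions and rng.random() < cluster.bias_1t:
                p5 = int(anchor_positions[rng.integers(len(anchor_positions))])
            elif iv.strand == "-":
                p5 = int(rng.integers(iv.start + length - 1, iv.end))
            else:
                p5 = int(rng.integers(iv.start, iv.end - length + 1))
            seq = _read_from(genome, iv.chrom, p5, length, iv.strand)
            if seq is not None:
                counter[seq] += 1
    # uniform degradation background
    n_bg = round(n_signal * background_fraction / (1 - background_fraction))
    chroms = sorted(genome)
    sizes = np.array([len(genome[c]) for c in chroms], dtype=float)
    for _ in range(n_bg):
        ci = int(rng.choice(len(chroms), p=sizes / sizes.sum()))
        chrom = chroms[ci]
        length = int(rng.integers(16, 31))
        start = int(rng.integers(0, len(genome[chrom]) - length + 1))
        seq = genome[chrom][start : start + length]
        if rng.random() < 0.5:
            seq = revcomp(seq)
        counter[seq] += 1
    return [
        CollapsedRead(seq, cnt, f"{tissue}_{i + 1}")
        for i, (seq, cnt) in enumerate(sorted(counter.items()))
    ]


# ---------------------------------------------------------------------------
# Truth serialization (JSON + GFF3)


def write_truth(truth: TruthTable, outdir: str | Path) -> None:
    """Truth files: JSON (full round-trip) and a GFF3 view of the plants."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {
        "tissues": list(truth.tissues),
        "plants": [
            {
                "spec": asdict(p.spec),
                "interval": asdict(p.interval),
            }
            for p in truth.plants
        ],
        "pirna_clusters": [asdict(c) for c in truth.pirna_clusters],
        "gene_models": [
            {
                "transcript_id": m.transcript_id,
                "gene_id": m.gene_id,
                "chrom": m.chrom,
                "strand": m.strand,
                "exons": [asdict(e) for e in m.exons],
                "utr5": [asdict(u) for u in m.utr5],
                "utr3": [asdict(u) for u in m.utr3],
                "cds": [asdict(c) for c in m.cds],
            }
            for m in truth.gene_models
        ],
    }
    (outdir / "truth.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
    records = [
        (
            p.interval,
            "miRNA_hairpin",
            {
                "ID": p.spec.id,
                "context": p.spec.context,
                "mirtron": "true" if p.spec.context == "MIRTRON" else "false",
                "conserved": str(p.spec.conserved).lower(),
            },
        )
        for p in truth.plants
    ] + [
        (c.interval, "piRNA_cluster", {"ID": c.id, "bias_1t": str(c.bias_1t)})
        for c in truth.pirna_clusters
    ]
    (outdir / "truth.gff3").write_text(to_gff3(records, source="synthetic"))


# ---------------------------------------------------------------------------
# Bundled demo study: 3 chromosomes x 200 kb, 30 planted miRNAs (3 of them
# miRtrons) across 4 genomic contexts, 9 tissue libraries, 2 testis-
# restricted piRNA clusters.

DEMO_N_CHROM = 3
DEMO_CHROM_LEN = 200_000
DEMO_GC = 0.41

# (id, context, conserved, in_existing_annotation, special)
_DEMO_PLAN: list[tuple[str, str, bool, bool, str]] = [
    ("P01", "INTRON", True, True, ""),
    ("P02", "EXON", True, True, ""),
    ("P03", "UTR", True, True, ""),
    ("P04", "INTERGENIC", True, True, ""),
    ("P05", "INTRON", True, True, ""),
    ("P06", "EXON", True, True, ""),
    ("P07", "UTR", True, True, ""),
    ("P08", "INTERGENIC", True, True, ""),
    ("P09", "INTRON", True, True, ""),
    ("P10", "EXON", True, False, "jitter_high"),
    ("P11", "UTR", True, False, "jitter_high"),
    ("P12", "INTERGENIC", True, False, "single_arm"),
    ("P13", "INTERGENIC", True, False, "silent"),
    ("P14", "MIRTRON", True, True, ""),
    ("P15", "INTRON", True, False, "switch"),
    ("P16", "INTERGENIC", True, False, "switch"),
    ("P17", "EXON", True, True, "nta_mixed"),
    ("P18", "INTERGENIC", True, True, "nta_u"),
    ("P19", "MIRTRON", False, False, ""),
    ("P20", "MIRTRON", False, False, ""),
    ("P21", "INTRON", False, False, ""),
    ("P22", "INTRON", False, False, ""),
    ("P23", "EXON", False, False, ""),
    ("P24", "UTR", False, False, ""),
    ("P25", "UTR", False, False, ""),
    ("P26", "INTERGENIC", False, False, ""),
    ("P27", "INTERGENIC", False, False, ""),
    ("P28", "INTRON", False, False, "switch"),
    ("P29", "INTERGENIC", False, False, "switch"),
    ("P30", "EXON", False, False, ""),
]

_SWITCH_FRACTIONS = {
    "blood": 0.2,
    "heart": 0.2,
    "brain": 0.8,
    "lung": 0.8,
    "testis": 0.8,
}

_MISMATCH_POSITIONS = (5, 10, 16)  # interior, >= 5 nt from either arm end


def _random_arm(rng: np.random.Generator, length: int = 22) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _arm3_with_wobbles(arm5: str, k: int) -> str:
    """Imperfect arm: replace Watson-Crick partners with G·U wobbles.

    Wobbles keep every stem position pairable (so max-pair folding
    recovers the planted register) while breaking exact reverse
    complementarity, as real hairpin stems do; a non-pairing mismatch
    would instead let the fold trade the planted stem for scrambled
    loop-arm pairings.
    """
    arm3 = list(revcomp(arm5))
    L = len(arm5)
    chosen: list[int] = []
    for p in range(4, L - 4):  # interior only, spaced >= 3
        if arm5[L - 1 - p] in "GT" and all(abs(p - q) >= 3 for q in chosen):
            chosen.append(p)
        if len(chosen) == k:
            break
    for p in chosen:
        arm3[p] = "T" if arm5[L - 1 - p] == "G" else "G"
    return "".join(arm3)


def _draw_hairpin_parts(
    rng: np.random.Generator, loop_len: int, n_wobbles: int
) -> tuple[str, str, str]:
    """Draw (arm5, loop, arm3) whose precursor folds to the planted register.

    A planted ground-truth locus must *be* a valid hairpin, so draws whose
    maximum-pairing fold is not a single stem-loop with the intended
    terminal loop (long loops can occasionally out-pair the planted stem
    by zipping onto an arm tail) are rejected and redrawn.
    """
    from .fold import hairpin_metrics, nussinov_fold, validate_hairpin

    for _ in range(200):
        arm5 = _random_arm(rng)
        if sum(1 for p in range(4, 18) if arm5[21 - p] in "GT") < 3:
            continue
        arm3 = _arm3_with_wobbles(arm5, n_wobbles)
        loop = "C" + "".join(rng.choice(list("AC"), size=loop_len - 1))
        precursor = arm5 + loop + arm3
        fold = nussinov_fold(precursor)
        m = hairpin_metrics(fold)
        planted_loop = (len(arm5), len(arm5) + loop_len)
        if (
            m.single_stem
            and m.loop is not None
            and abs(m.loop[0] - planted_loop[0]) <= 2
            and abs(m.loop[1] - planted_loop[1]) <= 2
            and validate_hairpin(fold, (0, len(arm5)), (planted_loop[1], len(precursor)))
        ):
            return arm5, loop, arm3
    raise RuntimeError("could not draw a clean hairpin in 200 attempts")


def _demo_spec(index: int, seed: int) -> PlantSpec:
    pid, context, conserved, in_existing, special = _DEMO_PLAN[index]
    rng = np.random.default_rng([seed, 100 + index])
    loop_len = (16 if conserved else 10) + index % 5
    arm5, loop, arm3 = _draw_hairpin_parts(rng, loop_len, 1 + index % 3)
    strand = "-" if index % 3 == 0 else "+"

    expression: dict[str, int] = {}
    fractions: dict[str, float] = {}
    nta: dict[str, float] = {}
    jitter = DEFAULT_JITTER_PROB
    if special == "silent":
        pass
    elif special == "switch":
        for tissue, frac in _SWITCH_FRACTIONS.items():
            expression[tissue] = int(rng.integers(400, 900))
            fractions[tissue] = frac
    else:
        n_tissues = int(rng.integers(4, 7))
        chosen = rng.choice(len(TISSUES), size=n_tissues, replace=False)
        base_frac = 0.7 if index % 2 == 0 else 0.3
        if special == "single_arm":
            base_frac = 1.0
        if special in ("nta_mixed", "nta_u"):
            base_frac = 0.8
        for ti in sorted(chosen):
            tissue = TISSUES[int(ti)]
            expression[tissue] = int(rng.integers(300, 1500))
            fractions[tissue] = base_frac
        if special in ("nta_mixed", "nta_u"):
            expression["blood"] = 2500
            fractions["blood"] = base_frac
        if special == "jitter_high":
            jitter = 0.65
    if special == "nta_mixed":
        nta = {"U": 0.3, "A": 0.1}
    elif special == "nta_u":
        nta = {"U": 0.5}
    return PlantSpec(
        id=pid,
        context=context,
        arm5_seq=arm5,
        arm3_seq=arm3,
        loop_seq=loop,
        strand=strand,
        tissue_expression=expression,
        arm5_fraction=fractions,
        nta_fractions=nta,
        jitter_prob=jitter,
        conserved=conserved,
        in_existing_annotation=in_existing,
    )


def _cassette(model_id: str, plant: PlantedHairpin) -> GeneModel | None:
    """Host transcript realizing the plant's declared genomic context."""
    iv = plant.interval
    s, e, chrom, strand = iv.start, iv.end, iv.chrom, iv.strand
    context = plant.spec.context
    if context == "INTERGENIC":
        return None
    if context == "MIRTRON":
        exons = [
            GenomicInterval(chrom, s - 250, s, strand),
            GenomicInterval(chrom, e, e + 250, strand),
        ]
        return GeneModel(f"TX_{model_id}", f"G_{model_id}", chrom, strand, exons)
    if context == "INTRON":
        exons = [
            GenomicInterval(chrom, s - 400, s - 150, strand),
            GenomicInterval(chrom, e + 150, e + 400, strand),
        ]
        return GeneModel(f"TX_{model_id}", f"G_{model_id}", chrom, strand, exons)
    exon = GenomicInterval(chrom, s - 150, e + 150, strand)
    model = GeneModel(f"TX_{model_id}", f"G_{model_id}", chrom, strand, [exon])
    if context == "UTR":
        model.utr3.append(GenomicInterval(chrom, s - 20, e + 20, strand))
    return model


def build_demo_truth(seed: int = 42) -> tuple[dict[str, str], TruthTable]:
    """The bundled synthetic study: genome plus fully planted truth table."""
    genome = make_genome(DEMO_N_CHROM, DEMO_CHROM_LEN, DEMO_GC, seed)
    truth = TruthTable()
    rng = np.random.default_rng([seed, 7])
    for index in range(len(_DEMO_PLAN)):
        spec = _demo_spec(index, seed)
        chrom = f"chr{index % DEMO_N_CHROM + 1}"
        slot = index // DEMO_N_CHROM
        position = 12_000 + slot * 18_000 + int(rng.integers(0, 1500))
        plant = PlantedHairpin(spec, GenomicInterval(chrom, position, position + len(spec.precursor), spec.strand))
        plant_hairpin(genome, spec, chrom, position, truth)
        model = _cassette(spec.id, plant)
        if model is not None:
            truth.gene_models.append(model)
    truth.pirna_clusters = [
        PiRNAClusterSpec(
            "PIC1",
            GenomicInterval("chr2", 183_000, 185_000, "+"),
            bias_1t=0.8,
            tissue_expression={"testis": 1500},
        ),
        PiRNAClusterSpec(
            "PIC2",
            GenomicInterval("chr3", 183_000, 185_500, "-"),
            bias_1t=0.8,
            tissue_expression={"testis": 1200},
        ),
    ]
    return genome, truth


def generate_dataset(
    outdir: str | Path, seed: int = 42, depth_scale: float = 1.0
) -> dict[str, object]:
    """Write the full demo study to disk; returns the file layout.

    Produces genome FASTA, gene-annotation GTF, per-tissue collapsed read
    libraries, miRBase-style reference hairpin/mature FASTA for the
    conserved plants, an existing-annotation GFF3 covering a subset of
    them, and the truth files.
    """
    from .io import to_gtf  # deferred: io imports nothing from here

    outdir = Path(outdir)
    (outdir / "reads").mkdir(parents=True, exist_ok=True)
    genome, truth = build_demo_truth(seed)
    write_fasta(genome, outdir / "genome.fa")
    (outdir / "annotation.gtf").write_text(to_gtf(truth.gene_models))

    hairpins = {f"ref-{p.spec.id}": p.spec.precursor for p in truth.plants if p.spec.conserved}
    matures: dict[str, str] = {}
    for p in truth.plants:
        if p.spec.conserved:
            matures[f"ref-{p.spec.id}-5p"] = p.spec.arm5_seq
            matures[f"ref-{p.spec.id}-3p"] = p.spec.arm3_seq
    write_fasta(hairpins, outdir / "reference_hairpins.fa")
    write_fasta(matures, outdir / "reference_matures.fa")

    existing = [
        (p.interval, "miRNA", {"ID": f"known-{p.spec.id}"})
        for p in truth.plants
        if p.spec.in_existing_annotation
    ]
    (outdir / "existing_annotation.gff3").write_text(to_gff3(existing, source="mirbase-like"))

    read_paths = {}
    for tissue in truth.tissues:
        reads = simulate_reads(truth, genome, tissue, depth_scale, seed)
        path = outdir / "reads" / f"{tissue}.fa"
        write_collapsed(reads, path)
        read_paths[tissue] = str(path)
    write_truth(truth, outdir)
    return {
        "genome": str(outdir / "genome.fa"),
        "gtf": str(outdir / "annotation.gtf"),
        "reads": read_paths,
        "reference_hairpins": str(outdir / "reference_hairpins.fa"),
        "reference_matures": str(outdir / "reference_matures.fa"),
        "existing_annotation": str(outdir / "existing_annotation.gff3"),
        "truth": str(outdir),
    }


def _iv(d: dict) -> GenomicInterval:
    return GenomicInterval(d["chrom"], d["start"], d["end"], d["strand"])


def read_truth(outdir: str | Path) -> TruthTable:
    payload = json.loads((Path(outdir) / "truth.json").read_text())
    plants = []
    for p in payload["plants"]:
        sp = dict(p["spec"])
        sp["nta_fractions"] = dict(sp.get("nta_fractions", {}))
        plants.append(PlantedHairpin(PlantSpec(**sp), _iv(p["interval"])))
    clusters = [
        PiRNAClusterSpec(
            id=c["id"],
            interval=_iv(c["interval"]),
            bias_1t=c["bias_1t"],
            tissue_expression=c["tissue_expression"],
            length_range=tuple(c["length_range"]),
        )
        for c in payload["pirna_clusters"]
    ]
    models = [
        GeneModel(
            m["transcript_id"],
            m["gene_id"],
            m["chrom"],
            m["strand"],
            [_iv(e) for e in m["exons"]],
            [_iv(u) for u in m["utr5"]],
            [_iv(u) for u in m["utr3"]],
            [_iv(c) for c in m["cds"]],
        )
        for m in payload["gene_models"]
    ]
    return TruthTable(plants, clusters, models, tuple(payload["tissues"]))
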
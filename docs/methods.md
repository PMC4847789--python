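# Methods

This note documents the models, parameter choices and numerical conventions
behind `mirannot`, and what the synthetic validation does and does not show.

## Coordinates and sequence conventions

All in-memory coordinates are 0-based half-open on the forward strand;
GTF/GFF3 serializers convert to 1-based inclusive at the boundary and
nowhere else. Sequences are stored as DNA (U is converted to T on input, so
miRBase-style RNA references mix freely with genomic sequence). Reverse-
strand features keep forward-frame coordinates with a strand flag; the
precursor sequence of a minus-strand locus is the reverse complement of the
genomic substring, and per-position read profiles are expressed in precursor
(5'→3' transcript) orientation.

## Secondary structure: base-pair maximization

Hairpin structures are predicted by Nussinov dynamic programming over the
allowed pairs A·U, G·C and G·U with a minimum hairpin loop of 3 nt, and a
fixed traceback preference (pair the closing bases, else bifurcate at the
smallest split, else leave the right end unpaired) so dot-brackets are
bit-reproducible. The downstream curation rules use only geometric features
of the structure — which positions pair, where the terminal loop sits, the
paired fraction of each arm — for which a maximum-pairing structure is an
adequate surrogate for a thermodynamic fold; free energies are deliberately
out of scope. An externally computed dot-bracket (e.g. from an MFE folder)
can be wrapped via `fold_from_dot_bracket` without changing any downstream
contract.

Maximum-pairing structures of genomic sequence routinely contain isolated
one- or two-pair "helices" of noise. A stem is therefore defined as a helix
branch of at least `min_stem_pairs` (default 3) pairs, and a structure is a
*single stem-loop* iff exactly one hairpin loop is closed by such a branch.
This makes the single-stem test robust without affecting genuine two-stem
rejections (real side-stems carry ≥ 3 pairs).

`validate_hairpin` accepts a mature pair iff the fold is a single stem-loop,
each mature sits on its arm reaching at most `loop_overlap_max` (2) nt into
the terminal loop, at least `min_paired` (0.6) of each mature's bases are
paired, and the paired bases of each mature point predominantly (≥ 50%) into
the other mature. These numeric surrogates for a qualitative "consistent
structure" judgment are repository defaults, exposed in the config.

## Alignment

`align_all` is a complete ungapped matcher: every placement of every query
on either strand with at most k ∈ {0, 1} substitutions. Completeness comes
from pigeonhole seeding — the query is split into k+1 disjoint segments
(capped at 12 nt so one index serves all read lengths); any hit with ≤ k
mismatches preserves one segment exactly, and every candidate placement is
verified in full. Small targets are scanned directly. Reverse-strand hits
are reported in forward coordinates with a strand flag. The test suite
checks exact agreement with a naive Hamming scan on random instances.

Homology mapping (`map_hairpins`) is seeded ungapped *local* alignment:
12-mer anchors every 6 nt, and around each anchor the maximum-scoring
contiguous segment (match +1, mismatch −2). Hits are retained at segment
length ≥ 60 and identity ≥ 0.8 — a desk-scale replacement for a
database-size-dependent e-value cutoff; the identity default is a package
choice, exposed in config. Mature confirmation then requires a full mature
to align inside the hit with ≤ 1 mismatch and no gaps.

## Discovery

Same-strand 0-mismatch placements within `cluster_max_gap` (65 nt) merge
into read clusters; clusters below `discovery_min_cluster_count` (10) reads
are dropped, mirroring the minimum-abundance filters of published
predictors and avoiding pointless folding of single-read degradation
clusters. Each surviving cluster is excised with 20 nt flanks (clusters
wider than 300 nt yield one 5'- and one 3'-anchored window). A window
becomes a candidate iff, after trimming to the extent of its two most
abundant distinct read stacks, the trimmed sequence (50–300 nt) folds into
a single stem-loop with the two stacks on opposite arms. Trimming before
folding keeps the structural test about the processed hairpin: flank bases
would otherwise contribute arbitrary noise pairs of their own. Overlapping
candidate sets are merged strand-blind with provenance retained.

## Curation

Read profiles are computed per locus per tissue from the genomic 0-mismatch
alignments restricted to the locus — exactly equivalent to re-aligning
reads against the precursor string, since the precursor is the genomic
substring. Mature calling and the two-peak test use the all-tissue
aggregated profile; per-tissue profiles feed expression, arm dominance and
switching. Arms are divided at the terminal-loop midpoint.

The two-peak ("precise processing") defaults: window ±2 nt, peak fraction
≥ 0.75, ≥ 10 reads per arm. Confidence: HIGH iff two-peak ∧ structure ∧
both arms expressed; conserved loci failing any criterion are annotated LOW
on similarity alone, novel loci are reported only when HIGH. Arm switching
is flagged when tissues with ≥ 20 reads disagree on the sign of
(5p − 3p); exactly balanced tissues carry no vote.

## Genomic context and miRtrons

Classification uses ≥ 15% overlap of the *hairpin* length (the denominator
choice follows the rule's phrasing), precedence UTR > EXON > INTRON because
UTRs lie within exons and would otherwise vanish as a category; CDS rows
count as exonic. Overlap is strand-blind; the host transcript is recorded.
miRtron calls require intron length 50–120 bp, hairpin coverage ≥ 95% of
the intron, and the two read peaks' modal arm boundaries within
`mirtron_tail_max` (3) nt of the intron ends — the tail allowance
quantifies "short trimmed tail".

## isomiRs

Only single-base 3' extensions are modeled (+A, +U, other). A read equal to
mature+X is non-templated only when X differs from the genomic base
immediately 3' of the mature locus (strand-adjusted); templated extensions
count with the canonical reads, and at a chromosome edge the call is flagged
undetermined. Detection compares reads against the mature sequence directly
because addition-carrying reads do not map to the genome.

## piRNA clusters

Counts of multimapping reads are distributed across their placements in
proportion to the summed count of uniquely mapping reads starting within
±10 kb of each placement (uniform fallback when all densities are zero);
weights per read sum to 1, conserving totals exactly. Candidate clusters
merge 24–32 nt placements with gaps ≤ 500 bp and are accepted at span
≥ 1000 bp, ≥ 25 normalized hits, 1T-or-10A signature ≥ 0.5 (union, reads
< 10 nt excluded) and in-range size fraction ≥ 0.75; strand class is MONO
at ≥ 80% one-strand share. This is an openly simplified analogue of the
proTRAC-style caller: the original's density model, p-values and
distribution test are replaced by these four explicit filters. The size
range upper bound of 32 (vs the 24–30 nt biological prose) tolerates
generator length jitter.

## The synthetic study generator

The generator plants everything the pipeline is supposed to find, so every
stage can be validated against known truth. The bundled study:
3 chromosomes × 200 kb at GC 0.41, 30 planted stem-loops (arms 22 nt, loops
10–20 nt, 1–3 G·U wobbles per stem) across intron/exon/UTR/intergenic
contexts including 3 miRtrons whose precursor coincides exactly with a
50–120 bp intron; 18 plants form the conserved reference set (12 of them
also in the "existing annotation" input); 9 tissue libraries; 2 piRNA
clusters (2.0 and 2.5 kb) expressed only in testis with first-base-T bias
0.8.

Generative choices:

* Read 5' starts sit at the modal arm position; with probability
  `jitter_prob` a start shifts by a uniform magnitude 1–8 (sign uniform),
  and read length is arm length + {−1, 0, +1} with weights 0.2/0.6/0.2. At
  the default jitter 0.2 an arm keeps ~92% of its hairpin-aligned 5'-start
  mass within ±2 of the mode (clearly above the 0.75 threshold); at 0.6 it
  drops to ~71% (clearly below), so high-jitter plants exercise the LOW
  path. Two plants are simulated at jitter 0.65, one with single-arm
  expression, one silent.
* Arm imperfections are G·U wobbles rather than non-pairing mismatches:
  wobbles keep the planted register the maximum-pairing structure while
  breaking exact reverse complementarity (which would otherwise make arm
  reads map to both strands of the locus).
* Loops are drawn from {A, C} (no internal pairing possible) and start with
  C, so the base templated 3' of the 5p mature is never A or T and planted
  +A/+U isoforms are non-templated by construction. The draw is
  rejection-sampled until the precursor's fold is a single stem-loop with
  the terminal loop at the planted position — a ground-truth hairpin must
  itself be a structurally valid hairpin.
* Non-templated additions affect 5p-arm reads: each is, with the configured
  probabilities, emitted as the exact mature plus one 3' A or T; detected
  counts are Binomial(N₅p, p), which the validation checks at 3σ.
* Arm-switching plants flip the 5p fraction across tissues (0.2 in blood
  and heart, 0.8 in brain, lung and testis); all other plants keep a
  constant per-tissue fraction so exactly the four switching plants are
  flagged.
* piRNA reads (24–30 nt) start, with probability equal to the bias, at a
  genomic position whose first transcribed base is T, so reads stay perfect
  genomic substrings; one cluster is plus-strand, one minus-strand.
* Background degradation is 5% of each library: uniform genomic positions
  and strands, lengths uniform 16–30 nt.

What the generator does **not** emulate: sequencing errors and quality
scores, realistic expression distributions (counts are set per tissue, not
drawn from a biological model), multi-nucleotide 3' tails, 5' isomiRs,
repeat-derived multimapping structure, and adapter read-through chemistry
(adapter trimming is exercised on constructed reads in unit tests).
Passing the planted-truth validation therefore demonstrates the pipeline's
rule logic and bookkeeping end to end, not its performance on real
libraries with error, repeat content and shallow expression.

## Problem sizes and determinism

The bundled study (600 kb genome, ~20–27 k reads per tissue) runs the full
pipeline in a few seconds on one CPU; oracle comparisons in the test suite
use targets of a few kb and sequences ≤ 25 nt, sizes at which exhaustive
references are exact and fast. All randomness flows from numpy Generators
seeded from the study seed (per-tissue and per-plant child seeds), so
regeneration and re-runs are byte-identical; pipeline stages are
file-backed and idempotent, and re-running a completed stage is a no-op
without `--force`.

## Known limitations

Base-pair maximization over-pairs relative to thermodynamic folding, so
`paired_fraction` thresholds are calibrated to it and should be revisited
if an MFE folder is plugged in. Homology identity 0.8 is a heuristic
stand-in for an e-value. The discovery stage is a transparent
reimplementation of the *role* of published predictors, not of their exact
rule sets or scoring. The piRNA caller omits ping-pong signature analysis
and repeat-annotation filtering. Cross-species homolog search reports only
ungapped local hits, so homologues with indels in the hairpin are missed.
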
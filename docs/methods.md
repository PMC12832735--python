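# Methods

## The rank-composition statistic

Cross-source EV cargo comparisons are confounded by platform, isolation
method and donor population, so the pipeline never compares expression
levels between cohorts. Each source is summarised by the per-feature mean of
log-transformed counts,

    μ_g = (1/n) Σ_{i=1..n} log(x_gi + 1),

and by its top-K set: the K features with the largest μ_g. For a pathway
with k member genes, the representation in a source is the count (and
percentage of k) of members inside that source's top-K set. The comparison
between sources is purely compositional: percent_A vs percent_B per pathway.

Assumptions worth stating:

- μ_g is computed on raw counts, exactly as the formula reads. Adding 1
  before the log keeps zero counts at score 0, and the score is 0 iff the
  feature is zero in every sample. A `library_size_normalize` flag rescales
  samples to the cohort's mean library size first; it is off by default and
  documented as a deviation from the plain formula.
- The log base is irrelevant to everything downstream: changing base
  rescales every μ_g by the same positive constant, so the ranking and the
  top-K membership are base-invariant (asserted on random matrices in the
  tests). Scores are reported in natural-log units.
- Ties at the top-K boundary are broken by ascending lexicographic feature
  ID. Any deterministic rule would do; lexicographic makes results
  reproducible across runs, platforms and pandas versions.
- The percentage denominator is always the full pathway size k, even when
  some members were never measured in a source. A `measured_a`/`measured_b`
  column counts pathway members present in each source's measured feature
  universe so the gap is visible rather than guessed at.

Display percentages are rounded to one decimal with round-half-even;
full-precision values are retained in the JSON reports.

### Optional inference

`proportion_test` runs a two-sided Fisher exact test on the 2×2 table
[in-top-K vs not] × [source A vs B]. It is an extension beyond descriptive
reporting and is off by default: the hypergeometric conditioning treats the
two sources as independent samples of the same k genes, which is at best an
approximation since the identical gene universe underlies both columns. No
multiple-testing correction is applied across pathways.

## ID harmonization

Feature universes from different studies rarely share a namespace. The rule
is: strip Ensembl-style version suffixes (text after the final '.' when the
prefix matches an `ENS…` accession), then, when symbol mapping is requested,
exact-match the stripped ID against the annotation's symbol column. IDs that
are already known symbols pass through unchanged, which makes the operation
idempotent. Unmapped IDs are excluded and *counted* — every harmonization
returns a report with input/output/dropped tallies; nothing is dropped
silently. Features present in one source and absent from the other are kept;
they simply cannot contribute to the other source's top-K set.

## Biotype composition and mapping summaries

A feature is "detected" in a sample iff its count ≥ `detect_threshold`
(default 1 — the weakest sensible rule for presence in a count table, and
configurable because detection conventions vary). Biotypes are canonicalised
onto a closed vocabulary (protein_coding, lncRNA, pseudogene, other);
features missing from the annotation are binned as `other` and counted with
a warning.

Cohort-level percentages are reported under two conventions that generally
disagree: the mean of per-sample percentages (each donor weighted equally)
and the ratio of mean counts (donors weighted by detected total). Published
cohort summaries do not always say which convention they used, and the two
can differ by several points, so both are emitted. A sample with nothing
detected gets NaN percentages and is excluded from the per-sample mean.

Mapping summaries add unique% + multi% into a total-mapped percentage per
sample and average across the cohort; raw read counts are converted to
percentages of each sample's total first, and a zero-read sample is an
error.

## Presence calling

**qPCR arrays.** Each gene × sample is assayed in duplicate. Present iff
both replicates have a Ct inside the dynamic window [18, 35], bounds
inclusive ("between 18 and 35" is read inclusively); a missing replicate —
including "Undetermined" wells, which the reader maps to missing — forces
absent. Widening the window can only convert absent→present (a tested
monotonicity invariant). Detection summaries count genes present in ≥ m
samples (default thresholds m = 1 and 10) with display percentages rounded
to the nearest integer.

**miRNA panels.** Negative-control probes define background: per sample,
mean + 2 SD of the control counts (population SD, so a single control row
still yields a defined threshold), averaged across samples. A miRNA is
expressed iff its mean count across samples strictly exceeds this
threshold. The 2-SD multiplier is a conventional digital-count background
rule and is configurable (`n_sd`); expressed miRNAs with mean count ≤ 100
carry a low-expression flag (strict '>' clears it). No positive-control or
housekeeping normalisation is applied — panel normalisation is upstream of
this package.

## Synthetic studies

The generator produces inputs with the statistical structure the analysis
assumes, so every stage is testable without sequencing data. It emulates a
two-cohort design of 15 vs 117 samples (small saliva-EV cohort against a
large public blood-EV cohort):

- Gene counts: negative binomial with var = μ + 0.3·μ², the standard
  overdispersed bulk RNA-seq model and the weakest assumption under which
  rank-based comparisons are meaningful. Baseline means are shared between
  sources and drawn log-normal(μ=1.0, σ=1.5), giving a realistically
  heavy-tailed abundance distribution over the default 5,000 genes — a
  deliberately scaled-down universe; rank-composition behaviour does not
  require transcriptome-scale feature counts. Per-sample library-size
  factors are log-normal(σ=0.2).
- Structural zeros: 5% of genes per source are set to zero mean in that
  source only, emulating biofluid-specific cargo (genes abundant in one
  source and essentially undetected in the other).
- Planted enrichment: one pathway's gene means are multiplied by a fold
  factor (default 8) in one source, creating a known top-K composition
  difference. Recovery (percent_A > percent_B for the planted pathway) is
  asserted over 100 seeded simulations, and the estimated representation
  difference increases monotonically in the fold factor over {1, 2, 8}.
- Biotype labels are drawn with proportions 0.681 / 0.157 / 0.090 / 0.072
  (protein_coding / lncRNA / pseudogene / other), matching reported
  saliva-EV cargo composition.
- qPCR panel: 94 genes × 15 samples, per-gene presence probabilities from a
  three-class mixture (never / sporadic / robust detection). Present wells
  draw Ct uniformly in [20, 33], away from the window edges; absent wells
  draw a missing replicate or an out-of-window Ct in [35.5, 40], so the
  calling rule recovers the planted truth exactly.
- miRNA panel: 827 probes × 6 samples with 286 expressed, six
  negative-control probes at Poisson mean 20, expressed means ≥ 200
  (log-normal spread) and unexpressed means of 3 — a separation construction
  under which the background filter recovers the expressed set exactly.
- Mapping stats: per-sample unique/multi percentages drawn around
  44.1% / 4.3%.

Seeds are mandatory (no default), all child streams derive from the one
seed, and identical configurations produce byte-identical study directories.

What the generator does **not** emulate: batch effects, GC/length bias,
microbial contamination of the unmapped fraction, hybridisation chemistry,
or inter-gene correlation. Passing tests therefore demonstrate that the
pipeline's logic recovers signals of the assumed form; they do not validate
the biological findings on real cohorts, which would require the original
sequencing data.

## Numerical and degenerate-input choices

- Validation is hard: negative counts, duplicate IDs, malformed GMT lines,
  replicate indices outside {1, 2} and empty files raise errors naming the
  offending cell or line.
- Fractional counts are allowed (multi-mapping reassignment produces them);
  only non-negativity is enforced.
- An all-zero sample yields NaN composition percentages rather than a fake
  zero split; an empty presence matrix yields zero counts at every
  threshold; K larger than the feature universe returns the whole universe.
- Reports are JSON with sorted keys and TSV with fixed column order, so
  re-running a configuration on the same inputs is bitwise reproducible,
  and every report embeds the configuration that produced it.

## Problem sizes in the test suite

Unit tests run on matrices up to 50×10 against brute-force oracles; the
simulation-based tests use the default 5,000-gene universe with 100 seeds
for the enrichment-recovery rate and 12 seeds per fold for the
monotonicity check. These sizes were chosen so the full suite and the
reproduction script each complete in well under a minute of simulation time
while leaving the recovery assertions comfortably powered.
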
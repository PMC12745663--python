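# Methods

This note documents the statistical procedures senatlas implements, the
choices made where a published protocol leaves details open, and what the
synthetic-data generator does and does not emulate.

## Quality control

Cells pass when they satisfy all three of: genes detected > 350 (strict),
UMIs > 1000 (strict), and mitochondrial UMI fraction strictly below
`median + 5·MAD`. The median and MAD are computed over **all input cells
before any removal**, which makes the filter deliberately non-idempotent: a
second pass would recompute the threshold on the filtered population and can
remove more cells, so the pipeline applies it exactly once (this is asserted
by a test). The MAD is unscaled — the median of absolute deviations from the
median, with no 1.4826 normal-consistency factor — and both the multiplier
and the scale are configurable (`QCThresholds.mad_scale`). "Expressed"
means count > 0 throughout, for the per-cell gene count and for the
subsequent gene filter (genes kept when expressed in ≥ 20 cells, applied
after the cell filter). Mitochondrial genes are identified by a
case-insensitive `mt-` symbol prefix (the mouse convention), configurable in
the readers. The mito statistics are pooled across samples by default since
a per-sample convention is equally defensible; computing them per sample is
a caller-side loop over samples.

If every cell fails, the error names the filter that removed the most
cells, because the common cause (a degenerate MAD of zero when mito
fractions are identical, which makes the strict-below rule unsatisfiable)
is otherwise hard to diagnose.

## Single-sample running-sum score

For one cell and one gene set of size *m* in a universe of *N* genes, genes
are ordered by descending expression with ties broken by stable input gene
order. The gene at 1-based position *i* carries rank value *N − i + 1* and
weight *(N − i + 1)^α*. With *P_in(i)* the weight-normalised cumulative
fraction of set genes among positions 1..*i* and *P_out(i)* the unweighted
cumulative fraction of the *N − m* non-set genes, the score is

    S = Σ_{i=1}^{N} [ P_in(i) − P_out(i) ].

α defaults to 0.25; α = 0 gives the unweighted Kolmogorov–Smirnov-like
statistic. Because only within-cell ranks enter, any strictly increasing
per-cell transform of expression (library-size scaling, log1p) leaves the
score unchanged, so it is computed directly on counts. Numerical parity
with any particular external enrichment package is explicitly not a goal:
the senescent-cell caller consumes only the within-cell-type **order** of
scores, which is the contract the tests pin down (a brute-force enumeration
over all small sets of a toy matrix must agree to 1e-10).

Degenerate inputs are rejected: a set with no genes in the matrix, and a
set covering the whole universe (the non-set cumulative fraction is then
undefined).

## Module score

On log1p CP10K expression, genes are cut into `n_bins = 24` equal-frequency
bins by mean expression (stable ties). For each set gene, `n_ctrl = 100`
control genes are drawn from its bin with a seeded generator — without
replacement when the bin is large enough, with replacement otherwise — and
the score is mean(set genes) − mean(pooled control draws) per cell. The
control pool keeps duplicate draws rather than uniquifying them; this keeps
the per-bin expected contribution of each set gene's controls equal and
makes the null expectation exactly zero, at the cost of a small deviation
from tools that deduplicate. An independent implementation (scanpy's
`score_genes`) correlates with ours above 0.95 on simulated data and serves
as a cross-check in the test suite, never as the implementation.

## Unified senescence score

The six sets (SM, CA, GA, SE, SASP, IR) are scored per cell; cells are
stratified by cell type; within each stratum each set's scores are split at
the median. "Upper half" means **strictly greater** than the median, so
ties at the median fall in the lower half — a deterministic, documented
convention. A cell is senescent when at least *k* of six sets are in its
upper half. *k* = 6 is the default: it is the conservative reading
consistent with few-percent senescent fractions, and the flagged set is
then a subset of each set's strict upper half, bounding the flagged
fraction at 50% per cell type. For *k* < 6 no such bound exists (the union
of upper halves can cover nearly all cells), which is why *k* stays
configurable but defaulted to 6. Cell types with fewer than two cells are
skipped with a warning. Reported per-(cell type, age group) senescent
fractions and an optional within-cell-type z-normalisation of scores (a
monotone transform that cannot change any call) complete the stage.

## Transcriptional noise

Per cell type, with both compared age groups required to have ≥ 10 cells:

1. each group is capped at 300 cells by seeded uniform subsampling (groups
   below the cap contribute all cells);
2. all pooled cells are downsampled to the minimum library size in the
   stratum by a per-cell multivariate-hypergeometric draw (sampling UMIs
   without replacement from the cell's own counts; the minimum-size cell is
   untouched);
3. invariant genes are selected on the pooled stratum — zero-mean genes
   excluded, the rest ranked by mean into 10 near-equal blocks, and the
   `ceil(block_size × 0.10)` lowest-CV genes (sample sd / mean) kept per
   block, so every block contributes at least one gene and both age groups
   are measured on a single panel;
4. per-cell distances are computed on log1p counts over the invariant
   genes: by default the Euclidean distance to the **group centroid**; a
   `pairwise` mode (mean distance to the other cells of the group) is
   provided as an alternative, and both are tested. Group noise is the mean
   per-cell distance and the statistic is `log2(noise_aged / noise_young)`.

The log1p transform and the centroid reference are package choices —
reasonable defaults where a published protocol typically leaves both
unstated; pooled-stratum gene selection avoids comparing groups on
different panels. Zero young-group noise yields a missing ratio with a
warning rather than an infinity.

## Composition testing with LTSR

Per cell type, per-sample cell counts are modelled as Poisson with log
link, offset log(total cells in the sample), and a binary group covariate;
the estimate and its Fisher-information SE come from the ML fit and are
converted to log2. The local true sign rate

    LTSR = Φ(|β̂| / SE) ∈ [0.5, 1]

is the probability the estimated direction of change is correct given its
mean and variance; LTSR > 0.9 declares a change. A cell type entirely
absent from one group is fitted after adding 0.5 to every sample's count
(continuity correction) and flagged in the output. The fixed-effect GLM is
a deliberate simplification of a mixed model with sample-level random
effects: with two or three samples per group a random-effect variance is
not estimable with any stability, while the LTSR definition and threshold
are preserved exactly. Calibration is checked empirically: under a
multinomial null the fraction of tests with LTSR > 0.9 sits near the
standard-normal tail value P(|z| > Φ⁻¹(0.9)) = 0.20, and a planted 2-fold
shift at realistic counts is detected essentially always.

## Marker detection

One-vs-rest, per gene, on log1p CP10K expression: a two-sided Wilcoxon
rank-sum test (normal approximation with tie correction and 0.5 continuity
correction, via `scipy.stats.mannwhitneyu`). `avg_logFC` follows the
Seurat-classic convention, `ln(mean(expm1(x_in)) + 1) −
ln(mean(expm1(x_out)) + 1)` (base configurable). Genes are screened before
testing at `max(pct_in, pct_out) > 0.20` (the fraction of cells with a
nonzero count in each group); BH adjustment runs across tested genes only.
A marker "passes" with `avg_logFC > 0.25`, adjusted p < 0.05 and the
min.pct screen. A gene identical in every cell has zero rank variance; its
p-value is defined as 1.

## Synthetic data generator

The generator emulates the minimal statistical structure the pipeline
assumes. Per cell, counts are negative binomial via the gamma–Poisson
mixture, `NB(mean μ_g, dispersion φ)` with variance `μ + φμ²`:

- baseline relative expression is log-normal across genes (σ = 1.5);
- four cell types (stromal, epithelial, NK/T, macrophage) each over-express
  40 marker genes 4-fold, renormalised within the type profile so library
  sizes stay on target across types;
- library sizes are log-normal (mean 5,000 UMIs, σ = 0.35);
- the six senescence sets (50 genes each, 10% shared core) are
  over-expressed 3-fold in flagged cells **without** renormalisation, so a
  flagged cell carries the extra set-gene mass; the planted fold is then
  recovered exactly in expectation by the flagged/unflagged count ratio,
  and the mean library shift at the default fractions is under 1%;
- senescent flags are Bernoulli per cell: stromal 0.03 (young, 3 months)
  rising to 0.10 (aged, 12 months) by default, other types 0;
- composition shifts come from age-specific cell-type proportions (stroma
  0.50 → 0.40, epithelium 0.20 → 0.25, macrophages 0.10 → 0.15);
- dispersion is φ = 0.25 for young cells, multiplied by 1.5 in aged cells,
  giving the noise statistic its signal;
- the mitochondrial fraction is Beta(10, 190) (mean 5%) with a 3%
  contaminant component Beta(8, 12) (mean 40%) that the MAD filter removes;
- everything is driven by one `numpy` generator, so equal seeds give
  bit-identical outputs.

Default sizes (2,000 genes, 3+3 samples of 500 cells) keep a full
generate–score–call cycle at a few seconds; the acceptance checks run the
noise and calibration studies at 800–1,000 genes and 8–20 seeds, sizes at
which the targeted effects are comfortably resolvable.

What the generator does **not** emulate — and hence what passing tests do
not establish about real tissue: gene–gene correlation beyond set- and
marker-level folds, batch or sample effects, ambient RNA and doublets
(upstream of this pipeline), zero-inflation beyond NB sampling, and
continuous senescence programs (flags are binary). Parameter-recovery
results on this generator demonstrate correctness of the statistics under
their own assumptions, not biological validity.

## Numerical conventions

Ties in expression ranks break by stable gene order everywhere (scoring,
block assignment, CV selection), making every statistic reproducible under
gene reordering on tie-free data. Seeds default to 0 and thread through
`PipelineConfig`; every stochastic operation (control-gene sampling,
subsampling, downsampling, simulation) accepts one. Medians use the
even-count midpoint convention of numpy. The USS caller, QC filters and
composition test are deterministic given their inputs.

## Known limitations

- The composition model ignores overdispersion between replicate samples;
  with strong sample-level clustering the LTSR is anti-conservative. A
  mixed or quasi-Poisson model is the upgrade path when sample numbers
  allow.
- The running-sum kernel is one member of the family of single-sample
  enrichment statistics; scores are comparable within a dataset, not
  across datasets or kernels.
- Hypergeometric downsampling discards information by design (it equalises
  depth rather than modelling it); noise ratios inherit its sampling
  variance, which the multi-seed tests average over.
- `find_markers` screens on expression fraction before testing; genes
  expressed in under 20% of both groups are reported untested (NaN
  p-values) rather than tested at low power.
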
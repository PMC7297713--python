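# Methods

## The multi-set model of an MFC cohort

A cohort is an ordered collection of matrices **X**ᵢ (Nᵢ cells × J
markers), one per biological sample, sharing one marker panel, each
labelled with a group id (0 = control/reference, ≥ 1 = responder).
Paired designs are represented by repeating a sample id across group
ids; uniqueness is enforced on the (sample_id, group_id) pair.  Cells
are rows and markers are columns everywhere.  Non-finite input values
are a hard error rather than being imputed: every statistic computed
downstream is a location or dispersion, and silent NaN handling would
corrupt them invisibly.

## Transforms

Fluorescence intensities are right-skewed and heteroscedastic.  Two
monotone transforms are offered: base-10 log (only for strictly positive
exports) and `asinh(x/c) = ln(x/c + √((x/c)² + 1))` (natural log), which
is linear for |x| ≪ c and logarithmic for |x| ≫ c and accepts the
negative values produced by background subtraction and compensation.
The cofactor defaults to c = 150, the customary value for conventional
fluorescence cytometers; it is global per run (a per-marker override
exists in the API for completeness).  The natural-log base is the
standard inverse-hyperbolic-sine identity; the base used is recorded in
the model's JSON metadata.

Poorly chosen cofactors can split one population into two density modes
near zero.  Rather than relying on visual histogram inspection,
`split_peak_diagnostic` counts local maxima of a Gaussian KDE per sample
before and after the transform (same *relative* bandwidth on both
scales) and flags samples whose mode count increased.  Mode counting on
a fixed 512-point grid is a pragmatic surrogate; it will merge modes
separated by less than the chosen bandwidth.

## Centering and scaling strategies

Four strategies for the location vector **m** and four for the scale
vector **s**, freely combinable (plus `scale="none"`):

* *standard_pooled*: statistics of the concatenated matrix.  Every cell
  carries equal weight, so samples with more cells dominate — the
  pooled mean shifts toward the largest sample.  This mirrors what
  concatenating pipelines do implicitly and is retained as the
  baseline.
* *multiset_whole*: **m** is the unweighted average of per-sample
  locations; **s** = √(average of per-sample variances).  Exactly
  invariant (at ddof = 0) under replicating any sample's cells.
* *control_based*: the same averages restricted to control samples; all
  groups are then expressed relative to the control reference, which
  emphasizes responder-specific mean shifts and dispersion changes.
* *per_sample*: each sample centered/scaled by its own statistics;
  removes technical per-sample offsets, at the cost of erasing any
  group-level mean difference (a documented, intentional trade-off —
  the right choice only when between-sample technical variability
  exceeds the biological group difference).

Estimators: mean/sd (classical) or median/MAD (robust).  MAD is
multiplied by 1.4826 (= 1/Φ⁻¹(3/4)) so it estimates the sd under
normality; the constant is recorded in model metadata.  The package
never switches estimators automatically; it warns when any sample has
fewer than 100 cells while mean/sd are selected.  The sd uses ddof = 1
by default (samples are finite draws); ddof = 0 is available and is
what makes replication invariance exact.  All quantities of interest in
the benchmark cohort are ratio-based and insensitive to this choice at
realistic N.

Two deliberate resolutions of ambiguities:

* The within-sample variance entering *multiset_whole*, *control_based*
  and *per_sample* scaling is always computed about **each sample's own
  location**, whatever centering preceded it.  This makes the scaling
  formulas composable with any centering (they "adapt unchanged"), and
  it reproduces the closed-form benchmark values below.  The
  alternative (variance about the global center) is not implemented.
* Zero-dispersion markers are a hard error naming the marker (and
  sample, for per-sample scaling).  A `drop-degenerate` style epsilon
  floor was rejected: it fabricates variance.  Combining whole-set
  centering with per-sample scaling triggers a warning, as this
  combination yields unpredictable downstream models.

### Fit/apply contract

`Preprocessor.fit()` computes all global vectors from the training
multi-set only and returns a `PreprocessModel` whose `apply()` uses the
stored vectors unchanged on any data with the same panel; per-sample
statistics are by definition recomputed on the applied data.  The
`fitted_on` list makes leakage auditable: in cross-validation the test
samples are provably absent from it.  Models serialize to JSON.

## Blockscaled SCA

Each preprocessed block is divided by √Nᵢ (blockscaling), the stacked
matrix is decomposed by thin SVD (numerically preferable to forming
XᵀX; the cross-product eigendecomposition survives only as the test
oracle), and per-cell scores are computed from the *unblockscaled* data
so that cells of large and small samples live on one score scale.  The
loading-relevant cross-products become Σᵢ XᵢᵀXᵢ/Nᵢ, which is invariant
under cell replication — the mechanism by which blockscaling removes
the influence of cell-count imbalance on the loadings.  An ablation
mode (`blockscaled=False`) exists to demonstrate that without it a
50×-replicated sample visibly rotates the loadings.

Column signs are fixed (largest-magnitude element of each loading
positive) so score plots are reproducible across runs and platforms.
Default K = min(J, 10); the explained-variance table is always printed
so users can choose K themselves.  Explained-variance ratios are
fractions of the total blockscaled variance (all singular values), and
the residual norm equals √(Σ_{k>K} σ²ₖ).

## Synthetic cohorts

The simulator draws, per sample, an optional technical offset
~ N(0, shift_sd) per marker, then Nᵢ cells from the group's
(axis-aligned) Gaussian mixture shifted by that offset.  Axis-aligned
covariance is intentional: the benchmark design has no printed
correlations.  Mixtures are supported but default to one component.
All draws derive from a single integer seed via `SeedSequence`, so a
spec regenerates bit-identically.

Three scenarios define the study conditions used throughout the tests:

* `scenario_benchmark(sigma=0.5, 8 per group, 10_000 cells)`: controls
  N((0, −2), (σ, 4σ)²), responders N((0, 2), (4σ, σ)²).  Only the mean
  gap (4 units on marker 2) and the sd pattern are identifiable from
  the known post-preprocessing statistics; σ = 0.5 and 8+8 × 10,000
  cells are this package's defaults, chosen because every target
  statistic is invariant to σ and to the per-group sample count as long
  as groups are balanced.  Closed forms: whole-set centering moves the
  group means to (0, ∓2); per-sample centering followed by whole-set
  scaling gives control sd (1, 4)/√(17/2) ≈ (0.343, 1.372) and the
  mirror image for responders; control-based scaling gives control sd
  (1, 1) and responder sd (4, 0.25).
* `scenario_unbalanced(base, i, factor=50)`: one sample with 50× more
  cells — the stress test under which pooled statistics shift and
  sample-weighted ones do not.
* `scenario_shifted_cohort(8 per group, 500 cells, shift_sd=2,
  effect=2)`: technical offsets in both groups plus a responder
  variance inflation; the regime where per-sample centering +
  control-based scaling is the recoverable optimum.  Defaults put the
  technical shift at twice the control within-sample sd — strong but
  not pathological drift — and the biological effect as a doubling of
  within-sample sd.

What the simulator does **not** emulate: fluorescence physics
(spillover, autofluorescence), heavy-tailed/zero-inflated marker
distributions, correlated marker panels, or real subpopulation
structure.  Passing tests therefore validate the *algebra and
contracts* of the preprocessing on data with known moments, not
biological recovery on real cytometry files.

## Evaluation harness

Per-sample features are normalized 2-D histograms (default 8 × 8) of
each sample's cells in the first two SCA components, over a grid
spanning the pooled *training* score range; held-out cells outside the
grid are clipped into edge bins.  Classification is nearest group
centroid (implemented directly — it is a three-line computation run
hundreds of thousands of times inside permutation loops) or
scikit-learn logistic regression.  The classifier is deliberately weak:
the harness quantifies what preprocessing exposes, not classifier
power.

Cross-validation is leave-one-out or stratified k-fold (k = 7, 50
repeats by default, matching common practice for cohorts of this size);
stratification is the default so control-based strategies are fittable
in every training fold, and an unstratified fold without controls fails
with guidance rather than silently refitting.  Every fold refits the
full pipeline — preprocessing, SCA, histogram grid — on training
samples only, and asserts that the held-out keys are absent from
`fitted_on`.

Permutation testing permutes group labels at the sample level (default
1000 permutations) and re-runs the entire pipeline per permutation,
preprocessing fit included (an honest null).  The p-value uses the
add-one estimator p = (1 + #{perm ≥ observed})/(1 + n_perm), which
cannot be zero; the raw count is printed alongside (`<k/n` form).
Because cross-validated accuracy is discrete, ties make the test
slightly conservative: on null cohorts the empirical P(p ≤ 0.1) sits
around 0.06–0.10.

## Problem sizes used in the test suite

The acceptance-style tests regenerate their cohorts at sizes chosen as
the package's own defaults for desk-scale verification: the benchmark
cohort at 8+8 × 10,000 cells; replication-invariance checks at 400
cells/sample with a 50× replicated sample; oracle equivalence on 100
random instances (≤ 5 markers, ≤ 20 cells/sample); permutation validity
as a meta-simulation of 200 null cohorts (6+6 samples × 50 cells,
3-fold × 2 repeats CV, 99 permutations each); and the shifted-cohort
direction check over 10 independent seeds.

## Known limitations

* FCS support covers list-mode files with float or uniform-width
  integer data; gain/log amplification ($PnE) and spillover matrices
  are read but not applied (inputs are assumed compensated and
  pre-gated, as is standard for exported analysis matrices).
* No logicle/biexponential transform and no automatic cofactor
  optimization.
* Binary group metrics (sensitivity/specificity) treat all responder
  groups as one positive class; multi-group cohorts are supported by
  the data model but evaluated as control vs non-control.
* The strategies correct location/scale structure only — no quantile
  normalization or density warping.
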
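# msflow — multi-set preprocessing for multicolor flow cytometry

Multicolor flow cytometry (MFC) measures several fluorescence markers on
each of thousands-to-millions of single cells per biological sample.  A
case–control study therefore produces a *multi-set* structure: one cell
× marker matrix **X**ᵢ per sample, all sharing a marker panel, each
sample labelled control (*g* = 0) or responder (*g* ≥ 1).  Most popular
analysis pipelines concatenate these matrices and center/scale the pooled
result — which silently lets the samples with the most cells dominate
every downstream model, and leaves sample-to-sample technical shifts
(laser drift, handling delays) in the data.

`msflow` implements the multi-set alternative for practitioners who
analyse such cohorts:

* **Transforms** — log₁₀ and inverse hyperbolic sine
  `asinh(x/c)` with cofactor *c* (default 150), plus a numeric
  split-peak diagnostic (KDE mode counting before vs after transform).
* **Four centering × four scaling strategies**, freely combinable, each
  with a classical (mean / sd) and a robust (median / MAD·1.4826)
  estimator:

  | strategy | location **m** | scale **s** |
  |---|---|---|
  | `standard_pooled`  | pooled over all cells | pooled sd |
  | `multiset_whole`   | mean of per-sample means, *m* = Σ mᵢ/I | √(mean of within-sample variances) |
  | `control_based`    | same, controls only | same, controls only |
  | `per_sample`       | each sample's own mᵢ | each sample's own sᵢ |

  The sample-weighted variants are exactly invariant under replicating
  any sample's cells — the pooled variant is not, which is the whole
  point.  Everything is packaged as `Preprocessor(ms, …).fit()` →
  `PreprocessModel.apply(…)` with a strict fit-on-train / apply-anywhere
  contract.
* **Blockscaled Simultaneous Component Analysis (SCA)** — each block is
  divided by √Nᵢ before a thin SVD, `X*₍sc₎ = T*P*ᵀ + E`, and per-cell
  scores come from the unblockscaled data, `T = X₍sc₎P*`; loadings are
  then independent of per-sample cell counts.
* **A synthetic cohort simulator** (Gaussian mixtures per sample,
  group-specific means/dispersions, per-sample technical offsets,
  unbalanced cell counts) and a **fold-safe evaluation harness**
  (leave-one-out / repeated k-fold CV, per-sample score-histogram
  features, nearest-centroid or logistic classification, sample-level
  label permutation testing).

## Worked example

```python
from msflow import (scenario_benchmark, simulate_multiset, Preprocessor,
                    TransformSpec, CenterSpec, ScaleSpec, SCA)

cohort = simulate_multiset(scenario_benchmark(seed=1))   # 8+8 samples x 10k cells
model = Preprocessor(cohort, TransformSpec("none"),
                     CenterSpec("per_sample"),
                     ScaleSpec("control_based")).fit()
print(model.summary())
res = SCA(model.apply(cohort), n_components=2).fit()
print(res.summary())
```

```
Multi-set preprocessing model
  transform : none
  centering : per_sample (mean)
  scaling   : control_based (sd, ddof=1)
  fitted on : 16 sample(s), 8 control(s)
  marker              location       scale
  M1                         -     0.49943
  M2                         -      2.0014

Simultaneous Component Analysis (blockscaled)
  cells x markers : 160000 x 2
  components      : 2
  residual norm   : 0
  component    sing.value  expl.var %    cum %
  1                11.626       94.08    94.08
  2                2.9158        5.92   100.00
```

The fitted scale vector is the control-group reference dispersion: the
control samples were simulated with within-sample sd (0.5, 2.0) and the
model recovers exactly that.  After this preprocessing the responder
cells have sd ≈ (4, 0.25) relative to the controls — the group effect
(axis-swapped dispersion) is exposed while every sample-specific offset
is gone.  The SCA table shows component 1 carrying the inflated
responder variance.

On a cohort with strong technical shifts, cross-validating the whole
pipeline shows why the strategy choice matters:

```python
from msflow import scenario_shifted_cohort, crossvalidate, CVScheme
ms = simulate_multiset(scenario_shifted_cohort(seed=1))
ev = crossvalidate(ms, TransformSpec("none"), CenterSpec("per_sample"),
                   ScaleSpec("control_based"), CVScheme("leave_one_out"))
print(ev.summary())    # accuracy : 100.0%  (pooled preprocessing: ~75%)
```

The same workflows are available from the shell:

```bash
msflow simulate --scenario benchmark --seed 1 --out raw/
msflow preprocess --manifest raw/manifest.csv --center sample \
       --scale control --transform none --out preprocessed/
msflow sca --manifest raw/manifest.csv --center sample --scale control \
       --transform none --components 2 --biplot-dims 1,2
msflow evaluate --manifest raw/manifest.csv --center sample \
       --scale control --transform none --cv loo --perms 1000 --seed 1
```

Real data enters through the same manifest mechanism, pointing at FCS
2.0/3.0/3.1 files or per-sample CSVs.

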
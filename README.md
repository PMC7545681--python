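# morphome

Quantitative analysis of **tumor budding** and **E-cadherin (ECad)
subcellular shifting** in periampullary adenocarcinoma — from per-cell
annotation tables to a stability-selected penalized Cox model, a
dichotomized *budding grade*, and multivariable survival reports.

## Who this is for

Pathology and biostatistics groups that quantify cohesive tumor cell
clusters (1–50 cells) at the invasion front and record, per cell, whether
ECad staining is membranous, mixed or cytoplasmic. Tumor budding — the
presence of small detached clusters — is an adverse prognostic feature,
and the shift of ECad from membrane to cytoplasm is a histologic surrogate
of epithelial–mesenchymal transition (EMT). The package turns those
annotations into a reproducible prognostic model and ships a synthetic
cohort generator, so every stage can be exercised and validated without
patient data.

## The model

Per patient, cluster sizes are binned into ten 5-cell categories; the
**morphome** is the 40-vector

* `buds.u` — number of clusters in the bin ending at *u* cells
  (u = 5, 10, …, 50), and
* `cyto.u`, `mix.u`, `memb.u` — fractions of cells in that bin's clusters
  with each ECad pattern.

Prognostic features are found by lasso-penalized Cox regression
(coordinate descent along a 100-point λ path; tenfold cross-validated
partial-likelihood deviance; Breslow ties), repeated ten times with
re-drawn folds: features nonzero at the tuned λ in **more than 80 %** of
repetitions are kept. An ordinary Cox fit on the kept features yields each
patient's linear predictor η = xᵀβ̂; the median split of η defines the
**low / high budding grade**, whose survival contrast is reported by
Kaplan–Meier medians and the log-rank test and tested against standard
clinicopathological covariates in a stepwise (AIC) multivariable Cox
model. The Cox, Kaplan–Meier, log-rank and Fisher-exact machinery is
implemented from first principles in `morphome.survival` /
`morphome.coxnet` (numba-accelerated coordinate descent).

## Worked example

```python
import warnings; warnings.simplefilter("ignore")
from morphome import SimulationConfig, run_matrix_pipeline, simulate_cohort

cohort = simulate_cohort(SimulationConfig(), seed=5, expand_cells=False)
res = run_matrix_pipeline(cohort.features, cohort.clinical, seed=5, R=10, V=10)
print(res.selected_fit.summary().round(3))
print(res.grade_report.table.round(1))
print(f"log-rank p = {res.grade_report.p:.2e}")
```

On the default cohort-analog configuration (171 patients, planted
log-hazards on `buds.10`, `buds.35`, `cyto.15`, `cyto.30`) this prints the
selected-feature hazard ratios — the rows below are an excerpt of the run
above; all four planted features are recovered with their planted
directions and p < 0.05, alongside some stably selected noise features
(see `docs/methods.md` on why the deviance-tuned lasso is permissive):

```
          coef  hazard_ratio  ci_low  ci_high      p
feature
buds.10  0.128         1.137   1.094    1.181  0.000
buds.35 -0.418         0.659   0.548    0.791  0.000
cyto.15  3.287        26.772   3.715  192.914  0.001
cyto.30  1.888         6.609   1.369   31.899  0.019
        n  n_events  median_os
grade
low    86        21        NaN
high   85        63       16.4
log-rank p = 2.17e-15
```

— the high budding grade holds half the cohort and a median overall
survival of 16 months, while the low grade's median is not reached (NaN)
within follow-up: exactly the planted prognostic structure. Shorter
narrative scripts live in `examples/` (one per capability: census
accounting, morphome features and the inverse count–size law, the
survival toolkit, penalized-path tuning, the full grading pipeline), and a
thin CLI (`morphome simulate|census|features|select|grade|report`) wraps
the same functions for shell use.

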
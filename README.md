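# lacthresh

Threshold ("two-piecewise") dose–response analysis of admission serum
lactate against 28-day mortality in elderly ICU sepsis cohorts.

Admission lactate marks tissue hypoperfusion, and its association with
short-term mortality in sepsis is positive but not linear: risk climbs
steeply through the mildly elevated range and flattens once lactate is
frankly high. `lacthresh` is a library for quantifying exactly that kind
of relationship in a per-patient flat table (one row per ICU stay with a
continuous exposure, a binary fixed-window outcome, and clinical
covariates). It is aimed at biostatisticians and intensive-care
researchers who want the full reporting pipeline — baseline table, crude
and adjusted odds ratios, smooth curves, threshold model, subgroups — as
reusable, tested code rather than a one-off script.

## The model

The core is a change-point logistic regression that keeps the log-odds
continuous in the exposure x while letting the per-unit slope change at a
turning point K:

    logit P(Y = 1 | x, Z) = α + β₁·min(x, K) + β₂·max(x − K, 0) + γ'Z

`exp(β₁)` is the per-unit odds ratio while x < K and `exp(β₂)` the
per-unit odds ratio at or above K. K is estimated by profile likelihood:
the model is refit at every candidate knot on a grid (default every
0.1 mmol/L between the 5th and 95th exposure percentiles) and K̂ is the
candidate maximising the likelihood. The gain over the ordinary one-line
model `α + β·x + γ'Z` is tested with a likelihood-ratio test (df = 1),
and a percentile bootstrap over row resamples — re-estimating K in every
replicate — gives a 95% CI for the knot.

Around that core the package provides:

* schema-validated cohort I/O with sequential exclusion filters, median
  imputation and empirical quartile binning (`lacthresh.cohort`);
* baseline ("Table 1") summaries with ANOVA / Kruskal–Wallis /
  chi-squared group tests chosen by each variable's declared summary
  style (`lacthresh.descriptives`);
* crude, age–sex-adjusted and fully adjusted logistic odds-ratio tables
  with Wald CIs, plus closed-form 2×2 estimators (`lacthresh.effects`);
* GAM-style smooth dose–response curves (natural cubic spline, 4 df) and
  SOFA-stratified curves (`lacthresh.smooth`);
* subgroup effects with median splits and interaction LRTs
  (`lacthresh.subgroups`);
* a synthetic eICU-like cohort generator with an embedded piecewise-logit
  truth, for end-to-end testing without credentialed data access
  (`lacthresh.simulate`);
* a run orchestrator writing a self-describing report bundle, with a thin
  `lacthresh` CLI on top (`lacthresh.pipeline`, `lacthresh.cli`).

## Worked example

`examples/` contains one short narrative script per capability. The
threshold analysis on a synthetic cohort at the default study conditions
(`python examples/03_threshold_analysis.py`) prints:

```
turning point K = 6.3 mmol/L (grid 1.10-6.95)
OR per mmol/L below K:     1.26 (1.19, 1.33)
OR per mmol/L at/above K:  1.08 (1.04, 1.13)
LRT one-line vs piecewise: 11.06, p = 0.0009
bootstrap 95% CI for K: (1.4, 6.9) [100 replicates, 0 failed]
  -> the wide CI reflects how weakly a mild slope change identifies the knot
```

Reading the numbers: below the estimated knot each 1 mmol/L of lactate
multiplies the odds of death by about 1.26 after adjustment; above it the
gradient flattens to about 1.08 per mmol/L, and the piecewise model fits
significantly better than a single straight line (LRT p < 0.001). The
bootstrap interval for K itself is wide — with a slope change this mild
(this cohort was generated with true per-unit ORs 1.33 below vs 1.11
above a knot at 3.7), the likelihood profile over candidate knots is
nearly flat, so single-cohort knot estimates scatter broadly even though
the segment slopes are estimated precisely. `examples/06_full_pipeline.py`
runs everything end to end and writes a `lacthresh_demo_run/` bundle
(baseline table, effect tables, threshold panel, curves, subgroups,
manifest).

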
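# Methods

## Cohort data model

A cohort is a flat per-stay table described by a variable schema: exactly
one continuous exposure (first serum lactate within 24 h of ICU
admission, mmol/L), one binary outcome (death within 28 days of
admission), covariates/stratifiers, and administrative columns (ICU
length of stay, sepsis flag, exposure-measurement count, time to death)
used only by filters. Validation enforces outcome values in {0, 1} and
strictly positive exposure values; empty cells and the tokens `NA`/`NaN`
(case-insensitive) are read as missing.

Exclusion filters — age < 65 years, ICU stay < 24 h, no sepsis
diagnosis, no lactate measurement — are applied **sequentially in that
order**, a row being counted against the first criterion it fails, so the
per-criterion removals plus the retained n partition the input. Whether
the original selection was sequential or a union is not knowable from a
final cohort size alone; the sequential flow-chart convention was chosen
and is what the exclusion report documents.

Missing covariates are median-imputed (continuous; the median of an even
count is the mean of the two central order statistics) or mode-imputed
(binary/categorical, ties toward the smallest value). Observed cells are
never altered, and the exposure and outcome are never imputed. Quartile
bins are the empirical 25/50/75 percentiles (linear-interpolation
quantiles) with intervals [min, q25), [q25, q50), [q50, q75), [q75, max]
— contiguous; printed-style labels like "Q2 1.5–2.0 / Q3 2.1–3.27"
reflect display rounding, not gaps.

## Descriptive tests

Baseline summaries use the test implied by each variable's declared
summary style: mean ± SD → one-way ANOVA, median (Q1–Q3) →
Kruskal–Wallis H, n (%) → Pearson chi-squared without continuity
correction (group tables at these sizes are large; a flag enables Yates
if wanted). Declaring normal-vs-skewed in the schema rather than testing
for it makes runs reproducible; the default schema marks WBC, BUN and
SOFA (and the exposure) as skewed. P-values display as "< 0.001" in
baseline tables and "< 0.0001" in effect tables.

## Effect models

Logistic models are fit by maximum likelihood (statsmodels `Logit`,
Newton scoring; a quasi-Newton retry distinguishes fragile designs from
genuine separation, which is reported as an error rather than returned as
inflated estimates). Rank-deficient designs raise an error naming the
aliased columns. Three adjustment sets mirror the conventional reporting
layout: crude; model I (age, gender); model II (age, gender, COPD, CHF,
AMI, DM, heart rate, temperature, hemoglobin, potassium, RBC, sodium,
WBC, bicarbonate, RDW, BUN, APACHE IV, SOFA, unit type). Categorical
covariates are reference-coded with the largest level (medical-surgical
ICU) as reference. Continuous covariates enter linearly and unscaled.

All intervals are Wald: OR = exp(β), CI = exp(β ± z·SE) with
z = 1.959964 (six decimals avoid last-digit drift against printed
2-decimal CIs). The closed-form 2×2 odds ratio with the Woolf log-SE is
provided as an independent oracle; on a saturated 2×2 the GLM reproduces
it to 1e-6 relative, which the tests assert. Proportions use the
normal-approximation CI clipped to [0, 1].

## Threshold (turning-point) analysis

The two-piecewise model uses the continuous hinge parameterisation
min(x, K) / max(x − K, 0), which forces the logit to be continuous at K
(no jump term) and makes exp of each hinge slope a per-unit OR on its
side of the knot. For fixed K this is an ordinary logistic fit; K itself
is estimated by grid search maximising the profile log-likelihood.

Numerical choices:

* **Grid**: multiples of 0.1 mmol/L between the 5th and 95th exposure
  percentiles — 0.1 matches the 1-decimal resolution at which knots of
  this kind are reported; the percentile bounds keep both segments
  populated. Ties break toward the smallest K. Candidates whose fit fails
  (a segment without both outcome classes, separation) are skipped and
  counted.
* **LRT**: 2·(LL_piecewise − LL_linear) referred to chi-squared with
  df = 1 (the added slope-change parameter). This common convention does
  not account for the estimation of K and is therefore mildly
  anticonservative; `bootstrap_lrt_p` offers a parametric-bootstrap
  p-value (outcomes resampled from the fitted one-line model, grid search
  repeated per replicate) for a calibrated alternative.
* **Bootstrap CI for K**: percentile interval over row resamples with
  replacement, n rows each, K re-estimated by full grid search per
  replicate. Failed replicates are dropped and counted; more than 20%
  failures aborts with diagnostics. The seed is mandatory — there is no
  silent default. Default 500 replicates.

A structural caveat documented deliberately: when the slope change is
mild (e.g. per-unit ORs 1.33 vs 1.11), the profile likelihood over K is
nearly flat, so the knot is weakly identified. Simulation at those
conditions with n ≈ 5,000 gives a median absolute knot error around
0.6 mmol/L, shrinking only slowly with n. Post-selection segment
estimates taken at K̂ are correspondingly biased away from the generative
slopes (the below-knot slope steepens when K̂ falls short of the true
knot); unbiased parameter recovery is therefore assessed at a fixed knot,
and the acceptance script reports segment ORs re-estimated at the pooled
(median-over-cohorts) knot.

## Smooth curves

The dose–response curve comes from a logistic additive model: a natural
cubic spline in the exposure (patsy `cr`, default 4 df — the conventional
dose–response default, enough for one bend; natural splines are linear
beyond the boundary knots, which keeps the sparse right tail of a skewed
exposure under control) plus linear covariate terms, fit unpenalised so
the pointwise 95% band follows exactly from the Wald covariance of the
fitted coefficients. At `spline_df=1` the curve degenerates to the
straight-line logistic fit (asserted to 1e-6), giving the natural nested
reference; df = 2 is rejected (the natural-cubic basis needs ≥ 3).

The overall curve reports the **centered partial effect** f(x) − f(x̄) in
log-odds. Stratified curves (default split SOFA ≤ 5 vs > 5,
configurable) are fit independently per stratum on a shared grid spanning
the range observed in every stratum, and default to **absolute adjusted
log-odds** (covariates at their sample means) so that baseline-risk
differences between strata remain visible — a centered display would
cancel exactly the level shift the stratification is meant to show.

## Subgroups and interaction

Continuous stratifiers are dichotomised at their in-sample median (the
cut value is echoed in the output for reproducibility); binary ones split
at 0/1. Within-stratum models adjust for the covariate list minus the
stratifier itself, avoiding self-adjustment. Effect modification is
tested by LRT between the pooled adjusted model with and without
exposure × stratum product terms, df = strata − 1. A stratum whose model
cannot be fit is flagged with an absent estimate and the run continues.
No multiplicity correction is applied across subgroups.

## Synthetic cohort generator

Individual-level eICU-style data are credentialed-access, so the
generator is the package's test bed. It emulates the published cohort
marginals and drives the outcome through the same piecewise mechanism the
pipeline estimates, so every stage can be scored against an embedded
truth.

* **Exposure**: shifted log-normal, chosen because the published
  median/IQR (2.10, 1.50–3.27 mmol/L) are right-skewed; the three
  parameters are solved in closed form so the distributional quartiles
  match those three values exactly.
* **Covariates**: drawn independently with marginals matching the
  published baseline table (age truncated-normal with median ≈ 76 and
  IQR ≈ 70–83; comorbidity prevalences; normal vitals/labs; shifted
  log-normal WBC and BUN; rounded-gamma SOFA; ICU unit type at the
  published mix). Severity markers carry modest clinically plausible
  log-odds effects (e.g. per-point SOFA OR 1.15, per-degree temperature
  OR 0.88); the remaining covariates are null. No empirical copula is
  attempted: independent covariates suffice for testing estimator
  correctness but do **not** reproduce real cross-correlations (e.g.
  bicarbonate falling as lactate rises), so passing tests certify the
  estimators, not the epidemiology of any particular cohort.
* **Outcome**: Bernoulli with logit α + ln(1.33)·min(x, 3.7) +
  ln(1.11)·max(x − 3.7, 0) + γ'Z by default. The intercept α is
  calibrated by Brent root-finding **on the generating distribution**
  (a cached 400,000-draw Monte Carlo with a fixed internal seed), not on
  the realized sample — each cohort's realized event rate then
  fluctuates binomially around the 13.8% target, as real sampling would;
  calibrating per-sample would artificially shrink between-cohort
  variability and distort CI coverage. An unreachable target rate raises
  a calibration error.
* **Missingness**: completely at random per variable, applied after
  outcome generation, at the published per-variable fractions (e.g. RDW
  9.36%, APACHE IV 11.79%); MCAR matches the median-imputation remedy
  downstream. Optional stratum modifiers add intercept/slope shifts above
  a severity cut (used for effect-modification tests), and an
  `early_death_frac` knob concentrates a fraction of deaths before 24 h
  at the highest lactate values for the sensitivity variant.

All draws flow from one `numpy` Generator: a given seed reproduces a
cohort byte for byte.

## Pipeline, sensitivity, problem sizes

`run_pipeline` executes filter → impute → bin → baseline table → effect
models → threshold (+bootstrap) → curves → subgroups, each stage failing
independently, and writes TSV/CSV/JSON outputs plus a manifest with
per-stage row counts and SHA-256 checksums (no timestamps, so identical
configurations produce byte-identical bundles). Sensitivity variants
rerun the pipeline on a complete-case cohort (no imputation) or after
dropping deaths within 24 h, and record side-by-side deltas for K and the
segment ORs.

Test and acceptance simulations use study-size cohorts (n = 5,150) for
parameter-recovery runs, 100 replicates for recovery/coverage summaries,
500 replicates for interaction type-I calibration at n = 2,000, and
reduced settings (n ≈ 1,500–20,000, bootstrap 10–100 replicates, grid
step 0.2–0.5) for structural and contract checks; these sizes were chosen
to make the checks sharp at interactive runtimes. Adjusted analyses in
the recovery simulations condition on the nine covariates that carry
effects in the generator rather than the full model-II panel — with
independent covariates the additional null terms change nothing but the
runtime.

## Known limitations

* The knot's weak identification at mild slope changes (above) is a
  property of the model class, not of the implementation; expect wide
  bootstrap CIs for K on realistic data.
* The df = 1 LRT reference is anticonservative because K is estimated;
  use the bootstrap p-value when the decision is borderline.
* MCAR missingness plus median imputation slightly attenuates covariate
  coefficients; with covariates independent of the exposure this leaves
  exposure effects essentially unbiased, which would not hold under
  informative missingness.
* The generator's independent covariates cannot exhibit confounding, so
  crude ≈ age-sex-adjusted estimates in synthetic runs; adjusted-vs-crude
  gaps seen in real cohorts will not appear.
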
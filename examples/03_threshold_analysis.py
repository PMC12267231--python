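"""Turning-point (threshold) analysis on one synthetic cohort.

Profile-likelihood grid search for the knot, per-segment odds ratios,
likelihood-ratio test against the one-line model, and a percentile
bootstrap CI for the knot.
"""

from lacthresh import (
    BootstrapSettings, bootstrap_turning_point, default_config,
    find_turning_point, generate_cohort, impute_median, make_grid,
)

ADJUST = ("hr", "temperature", "potassium", "wbc", "bicarbonate", "rdw",
          "bun", "apache_iv", "sofa")

t = impute_median(generate_cohort(default_config(seed=42)).table)
grid = make_grid(t)  # every 0.1 mmol/L between the 5th and 95th percentiles
pw = find_turning_point(t, grid, ADJUST)

print(f"turning point K = {pw.K:.1f} mmol/L "
      f"(grid {grid.range[0]:.2f}-{grid.range[1]:.2f})")
print(f"OR per mmol/L below K:     {pw.or_below.odds_ratio:.2f} "
      f"({pw.or_below.ci_low:.2f}, {pw.or_below.ci_high:.2f})")
print(f"OR per mmol/L at/above K:  {pw.or_above.odds_ratio:.2f} "
      f"({pw.or_above.ci_low:.2f}, {pw.or_above.ci_high:.2f})")
print(f"LRT one-line vs piecewise: {pw.lrt_statistic:.2f}, p = {pw.lrt_p:.4f}")

ci, ks, n_failed = bootstrap_turning_point(
    t, grid, ADJUST, BootstrapSettings(replicates=100, seed=42))
print(f"bootstrap 95% CI for K: ({ci[0]:.1f}, {ci[1]:.1f}) "
      f"[{len(ks)} replicates, {n_failed} failed]")
print("  -> the wide CI reflects how weakly a mild slope change "
      "identifies the knot")
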
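"""Reproduce the published summary statistics from printed counts alone.

The pooled 28-day mortality rate with its normal-approximation CI, the
unadjusted quartile odds ratios versus the lowest lactate quartile, and
the chi-squared group test are all fully determined by the per-quartile
death/survivor counts, so they reproduce exactly.
"""

from lacthresh import odds_ratio_2x2, proportion_ci
from lacthresh.descriptives import chi_squared_test

deaths = {"Q1": 97, "Q2": 111, "Q3": 174, "Q4": 329}
survivors = {"Q1": 1177, "Q2": 1127, "Q3": 1176, "Q4": 959}

p, lo, hi = proportion_ci(sum(deaths.values()),
                          sum(deaths.values()) + sum(survivors.values()))
print(f"28-day mortality: {100 * p:.1f}% (95% CI {100 * lo:.2f}-{100 * hi:.2f})")
print("  -> pooled event rate over all 5,150 stays, Wald interval\n")

for q in ("Q2", "Q3", "Q4"):
    e = odds_ratio_2x2(deaths[q], survivors[q], deaths["Q1"], survivors["Q1"])
    print(f"{q} vs Q1: OR {e.odds_ratio:.2f} "
          f"({e.ci_low:.2f}, {e.ci_high:.2f}), p = {e.p_value:.4g}")
print("  -> unadjusted odds of death per lactate quartile, Q1 reference\n")

stat, df, p_chi = chi_squared_test([list(deaths.values()),
                                    list(survivors.values())])
print(f"mortality x quartile chi-squared: {stat:.1f} (df {df}), p = {p_chi:.3g}")
print("  -> mortality differs across lactate quartiles")
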
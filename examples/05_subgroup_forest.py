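"""Subgroup (forest-plot style) lactate effects with interaction tests.

Each continuous stratifier is split at its in-sample median; within each
stratum the adjusted per-unit lactate OR is estimated, and a likelihood-
ratio test for the lactate x stratum product term gives one interaction p
per stratifier.
"""

from lacthresh import default_config, generate_cohort, impute_median, subgroup_effects
from lacthresh.subgroups import forest_frame

ADJUST = ("hr", "temperature", "potassium", "wbc", "bicarbonate", "rdw",
          "bun", "apache_iv", "sofa")

t = impute_median(generate_cohort(default_config(seed=42)).table)
results = subgroup_effects(t, ["hr", "potassium", "sofa"], ADJUST)
print(forest_frame(results).to_string(index=False))
print("\n  -> per-stratum per-unit ORs with one interaction p per "
      "stratifier; the default generator builds in no effect modification, "
      "so interaction p-values should be unremarkable")
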
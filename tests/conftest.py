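import dataclasses

import pytest

import lacthresh as lt
from lacthresh.simulate import default_config, default_covariates

#: covariates carrying non-zero effects in the default generator; adjusting
#: for these recovers the conditional (generative) exposure effects
ADJUST = ("hr", "temperature", "potassium", "wbc", "bicarbonate", "rdw",
          "bun", "apache_iv", "sofa")


def make_cohort(n=2500, seed=42, effects=True, missing=True, imputed=True, **kw):
    cfg = dataclasses.replace(
        default_config(n=n, seed=seed),
        covariates=default_covariates(with_missing=missing, with_effects=effects),
        **kw)
    gen = lt.generate_cohort(cfg)
    return lt.impute_median(gen.table) if imputed else gen.table


@pytest.fixture(scope="session")
def cohort_full():
    """One study-size cohort at the default generative truth."""
    return make_cohort(n=5150, seed=11)


@pytest.fixture(scope="session")
def cohort_small():
    return make_cohort(n=2500, seed=42)


@pytest.fixture(scope="session")
def cohort_null():
    """Equal segment slopes: a one-line logit truth (no threshold)."""
    return make_cohort(n=3000, seed=12, effects=False,
                      or_below_true=1.27, or_above_true=1.27)
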
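"""Logistic effect models, closed-form 2x2 oracle, Wald intervals."""

import numpy as np
import pandas as pd
import pytest

import lacthresh as lt
from lacthresh.cohort import CohortTable, quartile_bin
from lacthresh.effects import (
    LogisticFit, ModelSpec, effect_table, expand_2x2, fit_logistic,
    fit_logistic_arrays, odds_ratio_2x2, proportion_ci,
)
from lacthresh.errors import (
    CollinearityError, DegenerateOutcomeError, LacthreshError, SeparationError,
)

# published quartile 2x2 tables (deaths/survivors vs the Q1 reference)
# with the odds ratios and Wald CIs printed for them
PUBLISHED_2X2 = [
    ((111, 1127, 97, 1177), (1.20, 0.90, 1.59)),   # Q2 vs Q1
    ((174, 1176, 97, 1177), (1.80, 1.38, 2.33)),   # Q3 vs Q1
    ((329, 959, 97, 1177), (4.16, 3.27, 5.30)),    # Q4 vs Q1
]


class TestOddsRatio2x2:
    @pytest.mark.parametrize("counts,expected", PUBLISHED_2X2)
    def test_published_quartile_odds_ratios(self, counts, expected):
        e = odds_ratio_2x2(*counts)
        assert (round(e.odds_ratio, 2), round(e.ci_low, 2),
                round(e.ci_high, 2)) == expected

    def test_symmetric_table_is_null(self):
        assert odds_ratio_2x2(1, 1, 1, 1).odds_ratio == pytest.approx(1.0)

    def test_zero_cell_rejected(self):
        with pytest.raises(LacthreshError):
            odds_ratio_2x2(0, 5, 5, 5)


class TestProportionCI:
    def test_published_mortality_rate(self):
        p, lo, hi = proportion_ci(711, 5150)
        assert round(100 * p, 1) == 13.8
        assert (round(100 * lo, 2), round(100 * hi, 2)) == (12.86, 14.75)

    def test_zero_events_clips_at_zero(self):
        p, lo, hi = proportion_ci(0, 100)
        assert p == 0 and lo == 0

    def test_half_and_half(self):
        p, lo, hi = proportion_ci(50, 100)
        assert (round(100 * lo, 1), round(100 * hi, 1)) == (40.2, 59.8)

    def test_empty_denominator_rejected(self):
        with pytest.raises(LacthreshError):
            proportion_ci(0, 0)


class TestFitLogistic:
    @pytest.mark.parametrize("counts,expected", PUBLISHED_2X2)
    def test_glm_matches_closed_form_on_2x2(self, counts, expected):
        y, X = expand_2x2(*counts)
        fit = fit_logistic_arrays(y, X)
        oracle = odds_ratio_2x2(*counts)
        assert np.exp(fit.params["exposed"]) == pytest.approx(
            oracle.odds_ratio, rel=1e-6)
        e = effect_table(fit, ["exposed"])[0]
        assert (round(e.odds_ratio, 2), round(e.ci_low, 2),
                round(e.ci_high, 2)) == expected

    def test_null_exposure_covered_by_ci(self):
        # permute the outcome so the exposure carries no signal
        from conftest import make_cohort
        base = make_cohort(n=10000, seed=42)
        rng = np.random.default_rng(2024)
        df = base.df.copy()
        df["mortality_28d"] = rng.permutation(df["mortality_28d"].to_numpy())
        t = CohortTable(df, base.schema)
        e = effect_table(fit_logistic(t, ModelSpec.crude()), ["lactate"])[0]
        assert e.ci_low <= 1.0 <= e.ci_high

    def test_single_class_outcome_rejected(self, cohort_small):
        df = cohort_small.df.copy()
        df["mortality_28d"] = 0.0
        with pytest.raises(DegenerateOutcomeError):
            fit_logistic(CohortTable(df, cohort_small.schema), ModelSpec.crude())

    def test_aliased_column_named(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"const": 1.0, "a": rng.normal(size=200)})
        X["b"] = 2.0 * X["a"]
        y = pd.Series((rng.random(200) < 0.3).astype(float))
        with pytest.raises(CollinearityError) as exc:
            fit_logistic_arrays(y, X)
        assert "b" in exc.value.aliased

    def test_complete_separation_flagged(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=300)
        X = pd.DataFrame({"const": 1.0, "x": x})
        y = pd.Series((x > 0).astype(float))
        with pytest.raises(SeparationError):
            fit_logistic_arrays(y, X)

    def test_adding_a_covariate_never_decreases_loglik(self, cohort_small):
        base = fit_logistic(cohort_small, ModelSpec(covariates=("age",)))
        bigger = fit_logistic(cohort_small, ModelSpec(covariates=("age", "sofa")))
        assert bigger.llf >= base.llf - 1e-8

    def test_quartile_model_matches_2x2_oracle(self, cohort_full):
        _, labels = quartile_bin(cohort_full)
        fit = fit_logistic(cohort_full, ModelSpec.crude("quartiles"), labels)
        y = cohort_full.df["mortality_28d"]
        for lab in ("Q2", "Q3", "Q4"):
            d1 = int(y[(labels == lab)].sum())
            s1 = int((labels == lab).sum() - d1)
            d0 = int(y[(labels == "Q1")].sum())
            s0 = int((labels == "Q1").sum() - d0)
            oracle = odds_ratio_2x2(d1, s1, d0, s0)
            got = np.exp(fit.params[f"lactate_{lab}"])
            assert got == pytest.approx(oracle.odds_ratio, rel=1e-6)


class TestEffectTable:
    def _fit(self, beta, se):
        params = pd.Series({"const": -2.0, "x": beta})
        cov = pd.DataFrame([[0.01, 0.0], [0.0, se ** 2]],
                           index=params.index, columns=params.index)
        return LogisticFit(params, cov, llf=-10.0, n_used=100, converged=True)

    def test_unit_se_interval(self):
        e = effect_table(self._fit(0.0, 1.0), ["x"])[0]
        assert e.odds_ratio == pytest.approx(1.0)
        assert e.ci_low == pytest.approx(0.1409, abs=2e-4)
        assert e.ci_high == pytest.approx(7.0993, abs=2e-3)

    def test_interval_widens_with_se(self):
        widths = [np.log(effect_table(self._fit(0.5, s), ["x"])[0].ci_high)
                  - np.log(effect_table(self._fit(0.5, s), ["x"])[0].ci_low)
                  for s in (0.1, 0.2, 0.4)]
        assert widths == sorted(widths)

    def test_unknown_term_rejected(self):
        with pytest.raises(KeyError):
            effect_table(self._fit(0.0, 1.0), ["nope"])
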
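"""Two-piecewise logistic model, profile search, LRT and bootstrap."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import lacthresh as lt
from lacthresh.effects import LogisticFit, effect_table
from lacthresh.errors import (
    CollinearityError, NestingError, SearchFailureError, SegmentDegeneracyError,
    ValidationError,
)
from lacthresh.threshold import (
    TERM_ABOVE, TERM_BELOW, BootstrapSettings, SearchGrid,
    bootstrap_turning_point, fit_linear, fit_piecewise_at, find_turning_point,
    hinge_design, lrt_linear_vs_piecewise, make_grid,
)

from conftest import ADJUST, make_cohort


@pytest.mark.parametrize("x,K,expected", [
    (2.0, 3.7, (2.0, 0.0)),
    (5.0, 3.7, (3.7, 1.3)),
    (3.7, 3.7, (3.7, 0.0)),  # continuity at the knot
])
def test_hinge_terms(x, K, expected):
    below, above = hinge_design(np.array([x]), K)
    assert (below[0], above[0]) == pytest.approx(expected)


class TestFitPiecewise:
    def test_equal_slope_truth_close_to_linear(self, cohort_null):
        pw = fit_piecewise_at(cohort_null, 3.7, ())
        lin = fit_linear(cohort_null, ())
        assert pw.llf - lin.llf < 0.5
        b1, b2 = pw.params[TERM_BELOW], pw.params[TERM_ABOVE]
        se_diff = np.sqrt(pw.cov.loc[TERM_BELOW, TERM_BELOW]
                          + pw.cov.loc[TERM_ABOVE, TERM_ABOVE]
                          - 2 * pw.cov.loc[TERM_BELOW, TERM_ABOVE])
        assert abs(b1 - b2) < 1.96 * se_diff

    def test_knot_below_exposure_range_is_collinear(self, cohort_small):
        with pytest.raises(CollinearityError):
            fit_piecewise_at(cohort_small, 0.1, ())

    def test_segment_without_both_classes_flagged(self):
        df = pd.DataFrame({
            "lactate": np.r_[np.linspace(1, 3, 50), np.linspace(4, 8, 50)],
            "mortality_28d": np.r_[np.zeros(50),
                                   np.tile([0.0, 1.0], 25)],
            "age": np.full(100, 70.0),
        })
        from lacthresh import schema as sc
        t = lt.CohortTable(df, [
            sc.VariableSchema("lactate", "exposure", "continuous"),
            sc.VariableSchema("mortality_28d", "outcome", "binary"),
            sc.VariableSchema("age", "covariate", "continuous")])
        with pytest.raises(SegmentDegeneracyError) as exc:
            fit_piecewise_at(t, 3.7, ())
        assert exc.value.side == "below"

    def test_recovers_generative_segment_ors_at_scale(self):
        t = make_cohort(n=20000, seed=3)
        fit = fit_piecewise_at(t, 3.7, ADJUST)
        below, above = effect_table(fit, [TERM_BELOW, TERM_ABOVE])
        assert below.ci_low <= 1.33 <= below.ci_high
        assert above.ci_low <= 1.11 <= above.ci_high


class TestFindTurningPoint:
    def test_single_candidate_grid_returns_it(self, cohort_small):
        grid = SearchGrid((3.0,), (2.9, 3.1), 0.1)
        pw = find_turning_point(cohort_small, grid, ())
        assert pw.K == 3.0

    def test_matches_brute_force_oracle(self, cohort_small):
        grid = make_grid(cohort_small, step=0.3)
        pw = find_turning_point(cohort_small, grid, ())
        # independent brute-force loop over every candidate
        best = None
        for K in grid.candidates:
            try:
                f = fit_piecewise_at(cohort_small, K, ())
            except Exception:
                continue
            if best is None or f.llf > best[1] + 1e-12:
                best = (K, f.llf)
        assert pw.K == best[0]
        assert pw.loglik_piecewise == pytest.approx(best[1], abs=1e-8)

    def test_profile_argmax_property(self, cohort_small):
        pw = find_turning_point(cohort_small, make_grid(cohort_small, step=0.3), ())
        assert (pw.profile["loglik"] <= pw.loglik_piecewise + 1e-10).all()

    def test_fitted_logit_continuous_at_knot(self, cohort_small):
        pw = find_turning_point(cohort_small, make_grid(cohort_small, step=0.3), ())
        b = pw.fit.params
        eps = 1e-9

        def logit(x):
            below, above = hinge_design(np.array([x]), pw.K)
            return (b["const"] + b[TERM_BELOW] * below[0]
                    + b[TERM_ABOVE] * above[0])
        assert logit(pw.K - eps) == pytest.approx(logit(pw.K + eps), abs=1e-7)

    def test_deterministic(self, cohort_small):
        g = make_grid(cohort_small, step=0.3)
        p1 = find_turning_point(cohort_small, g, ())
        p2 = find_turning_point(cohort_small, g, ())
        assert p1.K == p2.K and p1.loglik_piecewise == p2.loglik_piecewise

    def test_empty_grid_fails(self, cohort_small):
        with pytest.raises(SearchFailureError):
            SearchGrid((), (0, 1), 0.1)


class TestLRT:
    def _fit(self, llf, n=100):
        p = pd.Series({"const": 0.0})
        c = pd.DataFrame([[1.0]], index=p.index, columns=p.index)
        return LogisticFit(p, c, llf=llf, n_used=n, converged=True)

    def test_identical_fits_give_null(self):
        stat, p = lrt_linear_vs_piecewise(self._fit(-50.0), self._fit(-50.0))
        assert stat == 0 and p == 1

    def test_known_quantile(self):
        stat, p = lrt_linear_vs_piecewise(self._fit(-51.92), self._fit(-50.0))
        assert stat == pytest.approx(3.84, abs=1e-9)
        assert p == pytest.approx(0.0500, abs=1e-3)

    def test_nesting_violation_raises(self):
        with pytest.raises(NestingError):
            lrt_linear_vs_piecewise(self._fit(-50.0), self._fit(-51.0))

    def test_piecewise_truth_detected(self, cohort_full):
        pw = find_turning_point(cohort_full, make_grid(cohort_full), ADJUST)
        assert pw.loglik_piecewise >= pw.loglik_linear
        assert pw.lrt_p < 0.05


class TestBootstrap:
    def test_same_seed_reproduces_ci(self, cohort_small):
        grid = make_grid(cohort_small, step=0.5)
        s = BootstrapSettings(replicates=10, seed=77)
        ci1, ks1, _ = bootstrap_turning_point(cohort_small, grid, (), s)
        ci2, ks2, _ = bootstrap_turning_point(cohort_small, grid, (), s)
        assert ci1 == ci2 and np.array_equal(ks1, ks2)

    def test_degenerate_grid_collapses_ci(self, cohort_small):
        grid = SearchGrid((3.0,), (2.9, 3.1), 0.1)
        ci, ks, _ = bootstrap_turning_point(
            cohort_small, grid, (), BootstrapSettings(replicates=10, seed=5))
        assert ci == (3.0, 3.0)

    def test_strong_signal_ci_covers_truth(self):
        t = make_cohort(n=4000, seed=5, effects=False,
                        or_below_true=1.8, or_above_true=1.02)
        ci, ks, n_failed = bootstrap_turning_point(
            t, make_grid(t), (), BootstrapSettings(replicates=60, seed=9))
        assert n_failed == 0
        assert ci[0] <= 3.7 <= ci[1]

    def test_seed_is_mandatory(self):
        with pytest.raises(ValidationError):
            BootstrapSettings(replicates=10)
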
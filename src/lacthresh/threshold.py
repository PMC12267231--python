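"""Two-piecewise logistic threshold ("change-point") analysis.

The model keeps the logit continuous in the exposure x while letting the
per-unit slope change at a turning point K:

    logit P(death) = a + b_below * min(x, K) + b_above * max(x - K, 0) + g'Z

``exp(b_below)`` is the per-unit odds ratio while x < K, ``exp(b_above)``
the per-unit odds ratio at or above K. K itself is estimated by profile
likelihood over a grid of candidate values (default: every 0.1 mmol/L
between the 5th and 95th exposure percentiles), the improvement over the
one-line model is assessed with a likelihood-ratio test, and a percentile
bootstrap over row resamples gives a 95% CI for K.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable
from .effects import EffectEstimate, LogisticFit, effect_table, fit_logistic_arrays
from .errors import (
    LacthreshError,
    NestingError,
    SearchFailureError,
    SegmentDegeneracyError,
    UnstableBootstrapError,
    ValidationError,
)

log = logging.getLogger(__name__)

TERM_BELOW = "exposure_below_k"
TERM_ABOVE = "exposure_above_k"


def hinge_design(x, K: float):
    """Continuous hinge terms ``(min(x, K), max(x - K, 0))``.

    The implied logit is continuous at K; the first term's slope is the
    log-odds gradient below K, the second term's slope the gradient at or
    above K.
    """
    if not np.isfinite(K):
        raise ValidationError("turning point K must be finite")
    x = np.asarray(x, dtype=float)
    return np.minimum(x, K), np.maximum(x - K, 0.0)


@dataclass(frozen=True)
class SearchGrid:
    """Ascending candidate turning points inside a percentile range."""

    candidates: tuple[float, ...]
    range: tuple[float, float]
    step: float

    def __post_init__(self):
        c = np.asarray(self.candidates)
        if len(c) == 0:
            raise SearchFailureError("empty turning-point grid")
        if not np.all(np.diff(c) > 0):
            raise ValidationError("grid candidates must be strictly increasing")
        lo, hi = self.range
        if c[0] < lo - 1e-9 or c[-1] > hi + 1e-9:
            raise ValidationError("grid candidates outside the stated range")


def make_grid(t: CohortTable, low_pct: float = 5.0, high_pct: float = 95.0,
              step: float = 0.1) -> SearchGrid:
    """Candidate K values: multiples of ``step`` inside the percentile range."""
    x = t.df[t.exposure].dropna().to_numpy()
    lo, hi = np.percentile(x, [low_pct, high_pct])
    first = np.ceil(lo / step) * step
    cands = np.round(np.arange(first, hi + step / 2, step), 10)
    cands = cands[(cands >= lo - 1e-9) & (cands <= hi + 1e-9)]
    if len(cands) == 0:
        raise SearchFailureError(
            f"no grid candidate with step {step} inside [{lo:.3g}, {hi:.3g}]")
    return SearchGrid(tuple(float(c) for c in cands), (float(lo), float(hi)), step)


@dataclass(frozen=True)
class BootstrapSettings:
    """Bootstrap replication settings; the seed is mandatory."""

    replicates: int = 500
    seed: int | None = None
    level: float = 0.95

    def __post_init__(self):
        if self.replicates < 2:
            raise ValidationError("need at least 2 bootstrap replicates")
        if self.seed is None:
            raise ValidationError("bootstrap requires an explicit seed")


@dataclass
class PiecewiseFit:
    """Result of the threshold analysis: the full reporting panel."""

    K: float
    or_below: EffectEstimate
    or_above: EffectEstimate
    loglik_piecewise: float
    loglik_linear: float
    lrt_statistic: float
    lrt_p: float
    K_ci: tuple[float, float] | None = None
    fit: LogisticFit | None = None
    linear_fit: LogisticFit | None = None
    profile: pd.DataFrame | None = None
    skipped_candidates: list[float] = field(default_factory=list)


def _design_at(y: pd.Series, X_cov: pd.DataFrame, x: pd.Series, K: float
               ) -> tuple[pd.Series, pd.DataFrame]:
    below, above = hinge_design(x.to_numpy(), K)
    X = X_cov.copy()
    X.insert(1, TERM_BELOW, below)
    X.insert(2, TERM_ABOVE, above)
    return y, X


def _covariate_design(t: CohortTable, covariates: Sequence[str]
                      ) -> tuple[pd.Series, pd.DataFrame, pd.Series]:
    """Shared complete-case outcome, covariate design (with const), exposure."""
    from .effects import ModelSpec, build_design

    spec = ModelSpec(exposure="linear", covariates=tuple(covariates), name="linear")
    y, X = build_design(t, spec)
    x = X.pop(t.exposure)
    return y, X, x


def fit_piecewise_at(t: CohortTable, K: float,
                     covariates: Sequence[str] = ()) -> LogisticFit:
    """Logistic MLE with hinge terms at a fixed turning point K.

    Both exposure segments must contain events and non-events; otherwise a
    :class:`SegmentDegeneracyError` identifies the empty side.
    """
    y, X_cov, x = _covariate_design(t, covariates)
    for side, mask in (("below", x < K), ("above", x >= K)):
        seg = y[mask]
        if len(seg) and seg.nunique() < 2:
            raise SegmentDegeneracyError(
                f"segment {side} K={K} lacks both outcome classes", side=side)
    yk, Xk = _design_at(y, X_cov, x, K)
    fit = fit_logistic_arrays(yk, Xk, name=f"piecewise@{K:g}")
    fit.extra["K"] = K
    return fit


def fit_linear(t: CohortTable, covariates: Sequence[str] = ()) -> LogisticFit:
    """The nested one-line model: a single per-unit exposure slope."""
    y, X_cov, x = _covariate_design(t, covariates)
    X = X_cov.copy()
    X.insert(1, t.exposure, x)
    return fit_logistic_arrays(y, X, name="linear")


def _profile_search(y: pd.Series, X_cov: pd.DataFrame, x: pd.Series,
                    grid: SearchGrid) -> tuple[float, LogisticFit, list, list]:
    """Scan grid candidates, return argmax-likelihood K (smallest K on ties)."""
    best_K, best_fit = None, None
    profile, skipped = [], []
    for K in grid.candidates:
        for side, mask in (("below", x < K), ("above", x >= K)):
            seg = y[mask]
            if len(seg) == 0 or seg.nunique() < 2:
                skipped.append(float(K))
                break
        else:
            try:
                yk, Xk = _design_at(y, X_cov, x, K)
                fit = fit_logistic_arrays(yk, Xk, name=f"piecewise@{K:g}")
            except LacthreshError:
                skipped.append(float(K))
                continue
            profile.append((float(K), fit.llf))
            if best_fit is None or fit.llf > best_fit.llf + 1e-12:
                best_K, best_fit = float(K), fit
    if best_fit is None:
        raise SearchFailureError("no feasible turning-point candidate on the grid")
    return best_K, best_fit, profile, skipped


def lrt_linear_vs_piecewise(fit_lin: LogisticFit, fit_pw: LogisticFit,
                            df: int = 1) -> tuple[float, float]:
    """Likelihood-ratio test of the one-line vs the two-piecewise model.

    The statistic is 2 * (LL_piecewise - LL_linear) referred to chi-square
    with ``df`` = 1 (the added slope-change parameter). This conventional
    reference does not account for the estimation of K and is mildly
    anticonservative; see :func:`bootstrap_lrt_p` for a resampling p-value.
    """
    if fit_lin.n_used != fit_pw.n_used:
        raise NestingError("linear and piecewise fits use different rows")
    stat = 2.0 * (fit_pw.llf - fit_lin.llf)
    if stat < -1e-8:
        raise NestingError(
            f"piecewise log-likelihood {fit_pw.llf} below linear {fit_lin.llf}")
    stat = max(stat, 0.0)
    return stat, float(stats.chi2.sf(stat, df))


def find_turning_point(t: CohortTable, grid: SearchGrid | None = None,
                       covariates: Sequence[str] = ()) -> PiecewiseFit:
    """Profile-likelihood grid search for the turning point.

    Returns the full threshold panel: K-hat (argmax of the piecewise
    log-likelihood over the grid, smallest K on ties), per-segment odds
    ratios with Wald CIs, the LRT against the one-line model, and the
    likelihood profile over candidates. Deterministic for fixed input.
    """
    if grid is None:
        grid = make_grid(t)
    y, X_cov, x = _covariate_design(t, covariates)
    K, fit, profile, skipped = _profile_search(y, X_cov, x, grid)
    if skipped:
        log.warning("turning-point search skipped %d infeasible candidates", len(skipped))
    lin = _fit_linear_from(y, X_cov, x, t.exposure)
    stat, p = lrt_linear_vs_piecewise(lin, fit)
    below, above = effect_table(fit, [TERM_BELOW, TERM_ABOVE])
    return PiecewiseFit(
        K=K, or_below=below, or_above=above,
        loglik_piecewise=fit.llf, loglik_linear=lin.llf,
        lrt_statistic=stat, lrt_p=p, fit=fit, linear_fit=lin,
        profile=pd.DataFrame(profile, columns=["K", "loglik"]),
        skipped_candidates=skipped)


def _fit_linear_from(y, X_cov, x, exposure_name: str) -> LogisticFit:
    X = X_cov.copy()
    X.insert(1, exposure_name, x)
    return fit_logistic_arrays(y, X, name="linear")


def bootstrap_turning_point(t: CohortTable, grid: SearchGrid | None = None,
                            covariates: Sequence[str] = (),
                            settings: BootstrapSettings | None = None
                            ) -> tuple[tuple[float, float], np.ndarray, int]:
    """Percentile bootstrap 95% CI for the turning point.

    Each replicate resamples n rows with replacement and repeats the full
    grid search (K is re-estimated per replicate). Returns
    ``((lo, hi), K_hats, n_failed)``. Replicates whose search fails are
    dropped and counted; more than 20% failures raises
    :class:`UnstableBootstrapError`.
    """
    if settings is None:
        raise ValidationError("bootstrap settings (with seed) are required")
    if grid is None:
        grid = make_grid(t)
    y, X_cov, x = _covariate_design(t, covariates)
    rng = np.random.default_rng(settings.seed)
    n = len(y)
    y_a, x_a, X_a = y.to_numpy(), x.to_numpy(), X_cov.to_numpy()
    ks, n_failed = [], 0
    for _ in range(settings.replicates):
        idx = rng.integers(0, n, size=n)
        yb = pd.Series(y_a[idx])
        xb = pd.Series(x_a[idx])
        Xb = pd.DataFrame(X_a[idx], columns=X_cov.columns)
        try:
            K, _, _, _ = _profile_search(yb, Xb, xb, grid)
            ks.append(K)
        except LacthreshError:
            n_failed += 1
    if n_failed > 0.2 * settings.replicates:
        raise UnstableBootstrapError(
            f"{n_failed}/{settings.replicates} bootstrap replicates failed",
            n_failed=n_failed, n_total=settings.replicates)
    ks = np.asarray(ks)
    alpha = (1 - settings.level) / 2
    lo, hi = np.percentile(ks, [100 * alpha, 100 * (1 - alpha)])
    if n_failed:
        log.warning("bootstrap dropped %d failed replicates", n_failed)
    return (float(lo), float(hi)), ks, n_failed


def bootstrap_lrt_p(t: CohortTable, grid: SearchGrid | None = None,
                    covariates: Sequence[str] = (), replicates: int = 200,
                    seed: int | None = None) -> float:
    """Parametric-bootstrap p-value for the LRT under the one-line null.

    Outcomes are resampled from the fitted linear model, the grid search is
    repeated on each resample, and the p-value is the fraction of null LRT
    statistics at or above the observed one (with the +1 correction).
    """
    if seed is None:
        raise ValidationError("bootstrap requires an explicit seed")
    if grid is None:
        grid = make_grid(t)
    y, X_cov, x = _covariate_design(t, covariates)
    lin = _fit_linear_from(y, X_cov, x, t.exposure)
    K, fit, _, _ = _profile_search(y, X_cov, x, grid)
    obs, _ = lrt_linear_vs_piecewise(lin, fit)
    X_lin = X_cov.copy()
    X_lin.insert(1, t.exposure, x)
    p_hat = 1 / (1 + np.exp(-(X_lin.to_numpy() @ lin.params.to_numpy())))
    rng = np.random.default_rng(seed)
    exceed = 0
    done = 0
    for _ in range(replicates):
        yb = pd.Series((rng.random(len(y)) < p_hat).astype(float))
        try:
            linb = _fit_linear_from(yb, X_cov, x, t.exposure)
            _, fitb, _, _ = _profile_search(yb, X_cov, x, grid)
            statb, _ = lrt_linear_vs_piecewise(linb, fitb)
        except LacthreshError:
            continue
        done += 1
        if statb >= obs - 1e-12:
            exceed += 1
    if done == 0:
        raise UnstableBootstrapError("all null replicates failed", replicates, replicates)
    return (exceed + 1) / (done + 1)
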
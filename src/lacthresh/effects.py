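"""Logistic effect models: odds ratios with Wald CIs for mortality.

Three adjustment sets mirror the usual reporting convention for this
cohort:

* ``crude``    — exposure only;
* ``model_i``  — exposure + age and gender;
* ``model_ii`` — exposure + the full covariate panel (comorbidities,
  vitals, labs, APACHE IV, SOFA, unit type).

Estimation is maximum likelihood via ``statsmodels`` (Newton scoring on the
binomial log-likelihood). Wald intervals use z = 1.959964 throughout, which
reproduces printed 2x2-table quartile CIs exactly from their counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import QUARTILE_LABELS, CohortTable
from .errors import (
    CollinearityError,
    DegenerateOutcomeError,
    LacthreshError,
    SeparationError,
    ValidationError,
)

#: two-sided 95% normal critical value, kept at 6 decimals to avoid
#: last-digit drift in printed CIs
Z95 = 1.959964

MODEL_I_COVARIATES = ("age", "gender")
MODEL_II_COVARIATES = (
    "age", "gender", "copd", "chf", "ami", "dm", "hr", "temperature",
    "hemoglobin", "potassium", "rbc", "sodium", "wbc", "bicarbonate",
    "rdw", "bun", "apache_iv", "sofa", "unit_type",
)


@dataclass(frozen=True)
class EffectEstimate:
    """Odds ratio with 95% CI and two-sided Wald p — one table cell."""

    term: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float

    def __post_init__(self):
        if not (self.ci_low <= self.odds_ratio <= self.ci_high):
            raise ValidationError(
                f"CI ({self.ci_low}, {self.ci_high}) does not bracket "
                f"OR {self.odds_ratio} for {self.term!r}")
        if min(self.odds_ratio, self.ci_low, self.ci_high) <= 0:
            raise ValidationError(f"odds ratio quantities must be positive ({self.term!r})")


@dataclass(frozen=True)
class ModelSpec:
    """What to regress: exposure form + covariate adjustment set."""

    exposure: str | None = "linear"  # "linear", "quartiles", or None
    covariates: tuple[str, ...] = ()
    name: str = "custom"

    @classmethod
    def crude(cls, exposure="linear"):
        return cls(exposure=exposure, covariates=(), name="crude")

    @classmethod
    def model_i(cls, exposure="linear"):
        return cls(exposure=exposure, covariates=MODEL_I_COVARIATES, name="model_i")

    @classmethod
    def model_ii(cls, exposure="linear"):
        return cls(exposure=exposure, covariates=MODEL_II_COVARIATES, name="model_ii")


@dataclass
class LogisticFit:
    """Converged ML fit: coefficients, covariance, log-likelihood."""

    params: pd.Series
    cov: pd.DataFrame
    llf: float
    n_used: int
    converged: bool
    name: str = "fit"
    extra: dict = field(default_factory=dict)

    @property
    def terms(self) -> list[str]:
        return list(self.params.index)

    def se(self, term: str) -> float:
        return float(np.sqrt(self.cov.loc[term, term]))


def expand_categorical(col: pd.Series, name: str) -> pd.DataFrame:
    """Reference-code a categorical column; the largest level is reference."""
    counts = col.value_counts()
    ref = counts.index[0]
    levels = [lev for lev in counts.index if lev != ref]
    out = pd.DataFrame(index=col.index)
    for lev in levels:
        out[f"{name}[{lev}]"] = (col == lev).astype(float)
    return out


def build_design(t: CohortTable, spec: ModelSpec,
                 quartile_labels: pd.Series | None = None
                 ) -> tuple[pd.Series, pd.DataFrame]:
    """Assemble outcome vector and design matrix (complete cases only)."""
    df = t.df
    cols: list[pd.Series | pd.DataFrame] = []
    if spec.exposure == "linear":
        cols.append(df[t.exposure].rename(t.exposure))
    elif spec.exposure == "quartiles":
        if quartile_labels is None:
            raise ValidationError("quartile exposure requires quartile labels")
        for lab in QUARTILE_LABELS[1:]:  # Q1 is reference
            cols.append((quartile_labels == lab).astype(float).rename(f"{t.exposure}_{lab}"))
    elif spec.exposure is not None:
        raise ValidationError(f"unknown exposure form {spec.exposure!r}")
    for name in spec.covariates:
        if name not in df.columns:
            raise ValidationError(f"covariate {name!r} not in table")
        col = df[name]
        if col.dtype == object or str(col.dtype) == "string":
            cols.append(expand_categorical(col, name))
        else:
            cols.append(col.rename(name))
    X = pd.concat([pd.Series(1.0, index=df.index, name="const"), *cols], axis=1)
    y = df[t.outcome]
    keep = y.notna() & X.notna().all(axis=1)
    return y[keep].astype(float), X[keep].astype(float)


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy()
    rank = np.linalg.matrix_rank(arr)
    if rank < X.shape[1]:
        # identify aliased columns via pivoted-QR-style greedy scan
        aliased, kept = [], []
        for j, name in enumerate(X.columns):
            cand = arr[:, kept + [j]]
            if np.linalg.matrix_rank(cand) > len(kept):
                kept.append(j)
            else:
                aliased.append(name)
        raise CollinearityError(
            f"design matrix rank {rank} < {X.shape[1]} columns; aliased: {aliased}",
            aliased=aliased)


def fit_logistic(t: CohortTable, spec: ModelSpec,
                 quartile_labels: pd.Series | None = None) -> LogisticFit:
    """Maximum-likelihood logistic regression per the model spec.

    Raises :class:`DegenerateOutcomeError` when only one outcome class is
    present, :class:`CollinearityError` on rank deficiency (naming the
    aliased terms) and :class:`SeparationError` on (quasi-)complete
    separation rather than returning silently inflated estimates.
    """
    y, X = build_design(t, spec, quartile_labels)
    return fit_logistic_arrays(y, X, name=spec.name)


def fit_logistic_arrays(y: pd.Series, X: pd.DataFrame, name: str = "fit") -> LogisticFit:
    """Fit logistic MLE on a prepared outcome vector and design matrix."""
    if y.nunique() < 2:
        raise DegenerateOutcomeError("outcome has a single class; cannot fit")
    _check_rank(X)
    model = sm.Logit(np.asarray(y), np.asarray(X))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = None
        try:
            res = model.fit(disp=0, method="newton", maxiter=100, tol=1e-10)
        except Exception as e:  # Newton can fail on near-flat likelihoods
            if "separat" not in str(e).lower() and "Singular" not in str(e):
                raise
        if res is None or not res.mle_retvals.get("converged", False):
            # quasi-Newton retry distinguishes fragile-but-fittable designs
            # from genuine (quasi-)separation, which shows up as huge slopes
            res = model.fit(disp=0, method="bfgs", maxiter=500, gtol=1e-6)
    params = pd.Series(res.params, index=X.columns)
    if not res.mle_retvals.get("converged", False):
        raise SeparationError("logistic fit did not converge (possible separation)")
    slopes = params.drop("const", errors="ignore")
    if len(slopes) and np.abs(slopes).max() > 30:
        raise SeparationError(
            "implausibly large coefficient suggests complete or "
            f"quasi-complete separation: {slopes.abs().idxmax()}")
    cov = pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns)
    return LogisticFit(params=params, cov=cov, llf=float(res.llf),
                       n_used=int(len(y)), converged=True, name=name)


def effect_table(fit: LogisticFit, terms: Sequence[str] | None = None
                 ) -> list[EffectEstimate]:
    """Wald odds-ratio table: OR = exp(b), CI = exp(b +/- z*SE)."""
    if not fit.converged:
        raise ValidationError("effect table requires a converged fit")
    if terms is None:
        terms = [tm for tm in fit.terms if tm != "const"]
    out = []
    for term in terms:
        if term not in fit.params.index:
            raise KeyError(f"term {term!r} not in fit")
        b = float(fit.params[term])
        se = fit.se(term)
        z = b / se if se > 0 else np.inf
        p = float(2 * stats.norm.sf(abs(z)))
        out.append(EffectEstimate(term, float(np.exp(b)),
                                  float(np.exp(b - Z95 * se)),
                                  float(np.exp(b + Z95 * se)), p))
    return out


def odds_ratio_2x2(d1: int, s1: int, d0: int, s0: int,
                   term: str = "exposed_vs_reference") -> EffectEstimate:
    """Closed-form odds ratio for a 2x2 table with Woolf (log) Wald CI.

    ``d1/s1`` are deaths/survivors in the exposed group, ``d0/s0`` in the
    reference group. OR = (d1*s0)/(s1*d0); the CI is
    exp(ln OR +/- z * sqrt(1/d1 + 1/s1 + 1/d0 + 1/s0)).
    """
    counts = (d1, s1, d0, s0)
    if any(c <= 0 for c in counts):
        raise LacthreshError(
            "all four 2x2 cells must be positive; continuity corrections "
            "are out of scope for this estimator")
    or_ = (d1 * s0) / (s1 * d0)
    se = np.sqrt(sum(1.0 / c for c in counts))
    z = np.log(or_) / se
    p = float(2 * stats.norm.sf(abs(z)))
    return EffectEstimate(term, float(or_),
                          float(np.exp(np.log(or_) - Z95 * se)),
                          float(np.exp(np.log(or_) + Z95 * se)), p)


def proportion_ci(k: int, n: int) -> tuple[float, float, float]:
    """Proportion with normal-approximation 95% CI, clipped to [0, 1]."""
    if n <= 0:
        raise LacthreshError("proportion undefined for n = 0")
    if not 0 <= k <= n:
        raise ValidationError(f"need 0 <= k <= n, got k={k}, n={n}")
    p = k / n
    se = np.sqrt(p * (1 - p) / n)
    return p, float(max(0.0, p - Z95 * se)), float(min(1.0, p + Z95 * se))


def expand_2x2(d1: int, s1: int, d0: int, s0: int) -> tuple[pd.Series, pd.DataFrame]:
    """Expand 2x2 counts to per-subject outcome/indicator arrays.

    Convenience for checking that the saturated logistic fit reproduces the
    closed-form 2x2 odds ratio.
    """
    y = np.r_[np.ones(d1), np.zeros(s1), np.ones(d0), np.zeros(s0)]
    x = np.r_[np.ones(d1 + s1), np.zeros(d0 + s0)]
    X = pd.DataFrame({"const": np.ones_like(x), "exposed": x})
    return pd.Series(y), X
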
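"""Subgroup (stratified) lactate effects and interaction tests.

For each prespecified stratifier the cohort is split (continuous
stratifiers at their in-sample median, binary ones at 0/1), the adjusted
per-unit exposure odds ratio is estimated within each stratum, and effect
modification is assessed with a likelihood-ratio test between the pooled
adjusted model with and without exposure x stratum product terms
(df = number of strata - 1). Within-stratum models drop the stratifier
from their own covariate list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable
from .effects import EffectEstimate, ModelSpec, build_design, effect_table, \
    fit_logistic_arrays
from .errors import LacthreshError, StratificationError
from . import schema as sc

log = logging.getLogger(__name__)


@dataclass
class SubgroupResult:
    """Forest-plot row set for one stratifier."""

    stratifier: str
    cut_value: float | None  # median cut for continuous stratifiers
    strata: list[str]
    n_strata: list[int]
    estimates: list[EffectEstimate | None]  # None where the stratum fit failed
    interaction_p: float


def _stratum_labels(t: CohortTable, name: str) -> tuple[pd.Series, float | None]:
    if name not in t.df.columns:
        raise StratificationError(f"stratifier {name!r} not in table")
    col = t.df[name]
    if col.dropna().nunique() < 2:
        raise StratificationError(f"stratifier {name!r} is constant")
    v = sc.by_name(t.schema, name) if any(s.name == name for s in t.schema) else None
    if v is not None and v.kind == "binary":
        lab = pd.Series(np.where(col == 1, f"{name}=1", f"{name}=0"), index=col.index)
        lab[col.isna()] = None
        return lab, None
    cut = float(col.median())
    lab = pd.Series(np.where(col <= cut, f"low (<= {cut:g})", f"high (> {cut:g})"),
                    index=col.index)
    lab[col.isna()] = None
    return lab, cut


def _adjusted_effect(t: CohortTable, covariates: Sequence[str]) -> EffectEstimate:
    spec = ModelSpec(exposure="linear", covariates=tuple(covariates), name="stratum")
    fit = fit_logistic_arrays(*build_design(t, spec), name="stratum")
    return effect_table(fit, [t.exposure])[0]


def interaction_test(t: CohortTable, stratifier: str,
                     covariates: Sequence[str] = ()) -> float:
    """LRT p-value for exposure x stratum effect modification.

    Compares the pooled adjusted model with and without product terms
    between the exposure and the stratum indicator(s); df = strata - 1.
    """
    labels, _ = _stratum_labels(t, stratifier)
    covs = tuple(c for c in covariates if c != stratifier)
    spec = ModelSpec(exposure="linear", covariates=covs, name="pooled")
    y, X = build_design(t, spec)
    lab = labels.loc[X.index]
    keep = lab.notna()
    y, X, lab = y[keep], X[keep], lab[keep]
    strata = sorted(lab.unique(), key=str)
    if len(strata) < 2:
        raise StratificationError(f"stratifier {stratifier!r} has < 2 strata")
    X_base = X.copy()
    for s in strata[1:]:
        X_base[f"stratum[{s}]"] = (lab == s).astype(float)
    X_full = X_base.copy()
    for s in strata[1:]:
        X_full[f"{t.exposure}:stratum[{s}]"] = X[t.exposure] * (lab == s).astype(float)
    fit0 = fit_logistic_arrays(y, X_base, name="no_interaction")
    fit1 = fit_logistic_arrays(y, X_full, name="interaction")
    stat = max(0.0, 2.0 * (fit1.llf - fit0.llf))
    return float(stats.chi2.sf(stat, len(strata) - 1))


def subgroup_effects(t: CohortTable, stratifiers: Sequence[str],
                     covariates: Sequence[str] = ()) -> list[SubgroupResult]:
    """Per-stratum adjusted exposure ORs and one interaction p per stratifier.

    A stratum whose model cannot be fit (too small, separated) is flagged
    with an absent estimate; the run continues.
    """
    results = []
    for name in stratifiers:
        labels, cut = _stratum_labels(t, name)
        covs = tuple(c for c in covariates if c != name)
        strata = sorted(labels.dropna().unique(), key=str)
        ests, ns = [], []
        for s in strata:
            sub = CohortTable(t.df[labels == s].reset_index(drop=True), t.schema)
            ns.append(sub.n)
            try:
                ests.append(_adjusted_effect(sub, covs))
            except LacthreshError as e:
                log.warning("stratum %s/%s fit failed: %s", name, s, e)
                ests.append(None)
        p_int = interaction_test(t, name, covariates)
        results.append(SubgroupResult(name, cut, [str(s) for s in strata],
                                      ns, ests, p_int))
    return results


def forest_frame(results: Sequence[SubgroupResult]) -> pd.DataFrame:
    """Flatten subgroup results into a forest-style table."""
    rows = []
    for r in results:
        for s, n, e in zip(r.strata, r.n_strata, r.estimates):
            rows.append({
                "stratifier": r.stratifier,
                "stratum": s,
                "n": n,
                "odds_ratio": None if e is None else round(e.odds_ratio, 4),
                "ci_low": None if e is None else round(e.ci_low, 4),
                "ci_high": None if e is None else round(e.ci_high, 4),
                "p_value": None if e is None else round(e.p_value, 6),
                "interaction_p": round(r.interaction_p, 6),
            })
    return pd.DataFrame(rows)
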
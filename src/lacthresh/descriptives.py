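"""Baseline ("Table 1") summaries by exposure quartile with group tests.

Each variable is summarised per exposure-quartile group and compared across
groups with the test matching its declared summary style:

* ``mean_sd``     -> one-way ANOVA,
* ``median_iqr``  -> Kruskal-Wallis H,
* ``count_pct``   -> Pearson chi-squared (no continuity correction by
  default; group tables here are large).

The normal-vs-skewed choice is declared in the schema, not decided by a
normality test, so a given schema always produces the same table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import schema as sc
from ._format import format_count_pct, format_mean_sd, format_median_iqr, format_p
from .cohort import CohortTable
from .errors import DegenerateTableError


@dataclass
class GroupSummary:
    """One baseline-table row: per-group display cells, test name and p."""

    variable: str
    level: str | None  # category level for count_pct rows, else None
    cells: dict[str, str]  # group label -> formatted cell
    test_name: str | None
    p_value: float | None

    def formatted_p(self, floor: float = 1e-3) -> str:
        if self.p_value is None:
            return "-"
        return format_p(self.p_value, floor)


def chi_squared_test(counts) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence on an r x c count table.

    Returns ``(statistic, df, p)`` with statistic = sum (O-E)^2 / E,
    df = (r-1)(c-1) and an upper-tail chi-square p-value. No Yates
    correction. Raises :class:`DegenerateTableError` on a zero marginal.
    """
    obs = np.asarray(counts, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise DegenerateTableError(f"need an r x c table with r,c >= 2, got {obs.shape}")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise DegenerateTableError("contingency table has a zero marginal")
    stat, p, df, _ = stats.chi2_contingency(obs, correction=False)
    return float(stat), int(df), float(p)


def anova_test(groups: Sequence[np.ndarray]) -> float | None:
    """One-way ANOVA p-value; None when the variable is constant overall."""
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return None
    f, p = stats.f_oneway(*groups)
    return float(p)


def kruskal_test(groups: Sequence[np.ndarray]) -> float | None:
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return None
    h, p = stats.kruskal(*groups)
    return float(p)


def _group_arrays(col: pd.Series, labels: pd.Series, group_names: Sequence[str]):
    return [col[(labels == g) & col.notna()].to_numpy(dtype=float)
            for g in group_names]


def baseline_table(t: CohortTable, labels: pd.Series,
                   group_names: Sequence[str] | None = None,
                   include_outcome: bool = True) -> list[GroupSummary]:
    """Summarise every non-admin variable by exposure-quartile group.

    ``labels`` is the per-row group assignment from
    :func:`lacthresh.cohort.quartile_bin`. The exposure itself is skipped
    (it defines the groups). Binary and categorical variables produce one
    row per level with column percentages within group; the test row
    carries the chi-squared p for the whole variable.
    """
    if group_names is None:
        group_names = [g for g in pd.unique(labels.dropna())]
        group_names = sorted(group_names)
    if len(group_names) < 2:
        raise DegenerateTableError("need at least two groups for a baseline table")
    rows: list[GroupSummary] = []
    for v in t.schema:
        if v.role == "admin" or v.name == t.exposure or v.name not in t.df.columns:
            continue
        if not include_outcome and v.name == t.outcome:
            continue
        col = t.df[v.name]
        if v.summary_style == "count_pct":
            levels = sorted(col.dropna().unique(), key=lambda z: str(z))
            counts = np.array([[int(((labels == g) & (col == lev)).sum())
                                for g in group_names] for lev in levels], dtype=float)
            try:
                _, _, p = chi_squared_test(counts)
            except DegenerateTableError:
                p = None
            for i, lev in enumerate(levels):
                cells = {}
                for j, g in enumerate(group_names):
                    n_g = int(((labels == g) & col.notna()).sum())
                    cells[g] = format_count_pct(int(counts[i, j]), n_g)
                rows.append(GroupSummary(v.name, str(lev), cells,
                                         "chi_squared" if i == 0 else None,
                                         p if i == 0 else None))
        else:
            arrays = _group_arrays(col, labels, group_names)
            if any(len(a) == 0 for a in arrays):
                raise DegenerateTableError(
                    f"variable {v.name!r} has an empty group")
            if v.summary_style == "mean_sd":
                p = anova_test(arrays)
                cells = {g: format_mean_sd(a.mean(), a.std(ddof=1))
                         for g, a in zip(group_names, arrays)}
                rows.append(GroupSummary(v.name, None, cells, "anova", p))
            else:
                p = kruskal_test(arrays)
                cells = {g: format_median_iqr(*np.percentile(a, [50, 25, 75]))
                         for g, a in zip(group_names, arrays)}
                rows.append(GroupSummary(v.name, None, cells, "kruskal_wallis", p))
    return rows


def baseline_frame(rows: list[GroupSummary], p_floor: float = 1e-3) -> pd.DataFrame:
    """Render baseline-table rows as a DataFrame mirroring the report layout."""
    group_names = list(rows[0].cells.keys()) if rows else []
    records = []
    for r in rows:
        rec = {"variable": r.variable if r.level is None else f"{r.variable}: {r.level}"}
        rec.update({g: r.cells.get(g, "-") for g in group_names})
        rec["test"] = r.test_name or "-"
        rec["p_value"] = format_p(r.p_value, p_floor) if r.p_value is not None else "-"
        records.append(rec)
    return pd.DataFrame.from_records(records)
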
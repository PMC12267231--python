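"""Cohort table container, CSV I/O, exclusion filters, imputation, binning.

The in-memory cohort is a :class:`pandas.DataFrame` wrapped together with
its variable schema. All downstream modules (descriptives, effect models,
threshold search, smoothing) consume a :class:`CohortTable`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import schema as sc
from .errors import (
    DegenerateBinningError,
    SchemaError,
    UnimputableError,
    ValidationError,
)

#: Tokens treated as missing on CSV input (case-insensitive), plus empty cells.
MISSING_TOKENS = ["", "NA", "NaN", "nan", "na", "NAN"]

QUARTILE_LABELS = ("Q1", "Q2", "Q3", "Q4")


@dataclass
class CohortTable:
    """A validated per-patient flat table plus its schema.

    Invariants (enforced by :meth:`validate`): outcome values are 0/1 where
    observed; exposure values are strictly positive where observed; ``n``
    equals the number of rows.
    """

    df: pd.DataFrame
    schema: list[sc.VariableSchema] = field(default_factory=sc.default_schema)

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def exposure(self) -> str:
        return sc.exposure_name(self.schema)

    @property
    def outcome(self) -> str:
        return sc.outcome_name(self.schema)

    def validate(self) -> "CohortTable":
        sc.validate_schema(self.schema)
        missing = [v.name for v in self.schema
                   if v.role != "admin" and v.name not in self.df.columns]
        if missing:
            raise SchemaError(f"cohort table lacks schema columns: {missing}")
        y = self.df[self.outcome]
        bad = y.dropna()[~y.dropna().isin([0, 1])]
        if len(bad):
            raise ValidationError(
                f"outcome {self.outcome!r} has values outside {{0,1}}: "
                f"{sorted(bad.unique())[:5]}"
            )
        x = self.df[self.exposure].dropna()
        if (x <= 0).any():
            raise ValidationError(f"exposure {self.exposure!r} has non-positive values")
        return self

    def copy(self) -> "CohortTable":
        return replace(self, df=self.df.copy())


def read_cohort(path: str | Path, schema: Sequence[sc.VariableSchema] | None = None
                ) -> CohortTable:
    """Read and validate a cohort CSV.

    The file must be RFC-4180 delimited text with a header row containing
    every non-admin schema column. Unparseable numeric cells and the tokens
    in :data:`MISSING_TOKENS` become missing values; rows are never dropped
    here.
    """
    schema = list(schema) if schema is not None else sc.default_schema()
    sc.validate_schema(schema)
    df = pd.read_csv(path, na_values=MISSING_TOKENS, keep_default_na=False,
                     skipinitialspace=True)
    required = [v.name for v in schema if v.role != "admin"]
    absent = [c for c in required if c not in df.columns]
    if absent:
        raise SchemaError(f"input file lacks required columns: {absent}")
    for v in schema:
        if v.name not in df.columns:
            continue
        if v.kind in ("continuous", "binary"):
            df[v.name] = pd.to_numeric(df[v.name], errors="coerce")
        else:
            df[v.name] = df[v.name].astype("string").astype(object)
    return CohortTable(df, schema).validate()


def write_cohort(t: CohortTable, path: str | Path) -> None:
    t.df.to_csv(path, index=False)


@dataclass(frozen=True)
class ExclusionCriteria:
    """Sequential cohort exclusion filters.

    Defaults encode an elderly-sepsis ICU selection: age >= 65 years,
    ICU stay >= 24 h, a sepsis diagnosis, and at least one exposure
    (lactate) measurement in the first 24 h.
    """

    min_age: float = 65.0
    min_icu_hours: float = 24.0
    require_sepsis_flag: bool = True
    min_exposure_measurements: int = 1
    age_col: str = "age"
    icu_hours_col: str = "icu_los_hours"
    sepsis_col: str = "sepsis"
    exposure_count_col: str = "lactate_count"

    def __post_init__(self):
        if self.min_age < 0 or self.min_icu_hours < 0 or self.min_exposure_measurements < 0:
            raise ValidationError("exclusion thresholds must be non-negative")


def apply_exclusions(t: CohortTable, criteria: ExclusionCriteria | None = None
                     ) -> tuple[CohortTable, dict[str, int]]:
    """Apply exclusion criteria sequentially; return retained table + counts.

    Criteria are applied in the declared order (short stay is evaluated
    second to mirror the usual flow-chart: age, stay, sepsis, exposure);
    a row failing several criteria is counted at the first one it fails,
    so the per-criterion removals plus the retained n sum to the input n.
    """
    c = criteria or ExclusionCriteria()
    df = t.df
    steps: list[tuple[str, pd.Series]] = []
    if c.min_age > 0:
        if c.age_col not in df.columns:
            raise SchemaError(f"exclusion filter needs column {c.age_col!r}")
        steps.append((f"age_below_{c.min_age:g}",
                      ~(df[c.age_col] >= c.min_age)))
    if c.min_icu_hours > 0:
        if c.icu_hours_col not in df.columns:
            raise SchemaError(f"exclusion filter needs column {c.icu_hours_col!r}")
        steps.append((f"icu_stay_below_{c.min_icu_hours:g}h",
                      ~(df[c.icu_hours_col] >= c.min_icu_hours)))
    if c.require_sepsis_flag:
        if c.sepsis_col not in df.columns:
            raise SchemaError(f"exclusion filter needs column {c.sepsis_col!r}")
        steps.append(("no_sepsis_diagnosis", ~(df[c.sepsis_col] == 1)))
    if c.min_exposure_measurements > 0:
        if c.exposure_count_col in df.columns:
            fail = ~(df[c.exposure_count_col] >= c.min_exposure_measurements)
        else:
            # fall back to requiring an observed exposure value
            fail = df[t.exposure].isna()
        steps.append(("no_exposure_measurement", fail))

    removed: dict[str, int] = {}
    alive = pd.Series(True, index=df.index)
    for name, fail in steps:
        hit = alive & fail.fillna(True).astype(bool)
        removed[name] = int(hit.sum())
        alive &= ~hit
    out = CohortTable(df[alive].reset_index(drop=True), t.schema)
    return out, removed


def impute_median(t: CohortTable, columns: Sequence[str] | None = None) -> CohortTable:
    """Median-impute continuous covariates; mode-impute binary/categorical.

    Observed cells are never altered. The median of an even number of
    observed values is the mean of the two central order statistics. The
    exposure and outcome are never imputed. Raises
    :class:`UnimputableError` for an all-missing column.
    """
    df = t.df.copy()
    if columns is None:
        columns = [v.name for v in t.schema
                   if v.role in ("covariate", "stratifier") and v.name in df.columns]
    for name in columns:
        v = sc.by_name(t.schema, name)
        col = df[name]
        if col.isna().all():
            raise UnimputableError(f"column {name!r} has no observed values")
        if not col.isna().any():
            continue
        if v.kind == "continuous":
            fill = float(col.dropna().median())
        else:
            # mode; ties broken toward the smallest value for determinism
            fill = col.dropna().mode().iloc[0]
        df[name] = col.fillna(fill)
    return CohortTable(df, t.schema)


@dataclass(frozen=True)
class QuartileBinning:
    """Empirical quartile cutpoints of the exposure and the four bin labels.

    Bins are [min, q25), [q25, q50), [q50, q75), [q75, max]: left-closed,
    right-open except the last. The printed-style labels round the
    cutpoints for display; the bins themselves are contiguous.
    """

    cutpoints: tuple[float, float, float]
    labels: tuple[str, str, str, str] = QUARTILE_LABELS

    def __post_init__(self):
        c = self.cutpoints
        if not (c[0] < c[1] < c[2]):
            raise DegenerateBinningError(
                f"quartile cutpoints must be strictly increasing, got {c}")

    def assign(self, x: np.ndarray | pd.Series) -> pd.Series:
        x = pd.Series(np.asarray(x, dtype=float))
        idx = np.searchsorted(np.asarray(self.cutpoints), x.to_numpy(), side="right")
        out = pd.Series(pd.array([None] * len(x), dtype="object"), index=x.index)
        ok = ~x.isna()
        out[ok] = np.asarray(self.labels, dtype=object)[idx[ok.to_numpy()]]
        return out


def quartile_bin(t: CohortTable) -> tuple[QuartileBinning, pd.Series]:
    """Bin the exposure at its empirical 25/50/75 percentiles.

    Returns the binning and a per-row label series (missing exposure keeps
    a missing label). Raises :class:`DegenerateBinningError` when the
    exposure has fewer than four distinct observed values.
    """
    x = t.df[t.exposure].dropna()
    if x.nunique() < 4:
        raise DegenerateBinningError(
            f"exposure {t.exposure!r} has {x.nunique()} distinct values; need >= 4")
    cuts = tuple(float(q) for q in np.quantile(x.to_numpy(), [0.25, 0.50, 0.75]))
    binning = QuartileBinning(cuts)
    labels = binning.assign(t.df[t.exposure])
    labels.index = t.df.index
    return binning, labels


def group_sizes(labels: pd.Series) -> dict[str, int]:
    return {lab: int((labels == lab).sum()) for lab in QUARTILE_LABELS}
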
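"""Variable schema for ICU cohort tables.

A cohort is a flat per-stay table. Each column is described by a
:class:`VariableSchema` entry giving its role in the analysis (exposure,
outcome, covariate, stratifier, or administrative plumbing), its measurement
kind, and how it is summarised in a baseline ("Table 1") report.

The default schema describes an elderly-sepsis ICU cohort: first serum
lactate (mmol/L) as the continuous exposure, 28-day mortality as the binary
outcome, and the usual demographic/laboratory/severity covariates (age, sex,
comorbidities, vitals, labs, APACHE IV, SOFA, unit type).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .errors import SchemaError

ROLES = ("exposure", "outcome", "covariate", "stratifier", "admin")
KINDS = ("continuous", "binary", "categorical")
SUMMARY_STYLES = ("mean_sd", "median_iqr", "count_pct")


@dataclass(frozen=True)
class VariableSchema:
    """Description of one cohort column.

    Parameters
    ----------
    name : str
        Column name in the table.
    role : str
        One of ``exposure``, ``outcome``, ``covariate``, ``stratifier``,
        ``admin``. Admin columns (length of stay, flags) never enter models
        or baseline summaries.
    kind : str
        ``continuous``, ``binary`` or ``categorical``.
    units : str
        Free-text units, for display only.
    summary_style : str
        ``mean_sd`` (summarised as mean +/- SD, compared by one-way ANOVA),
        ``median_iqr`` (median (Q1-Q3), Kruskal-Wallis) or ``count_pct``
        (n (%), chi-squared test).
    """

    name: str
    role: str
    kind: str
    units: str = ""
    summary_style: str = "mean_sd"

    def __post_init__(self):
        if self.role not in ROLES:
            raise SchemaError(f"unknown role {self.role!r} for {self.name!r}")
        if self.kind not in KINDS:
            raise SchemaError(f"unknown kind {self.kind!r} for {self.name!r}")
        if self.summary_style not in SUMMARY_STYLES:
            raise SchemaError(
                f"unknown summary_style {self.summary_style!r} for {self.name!r}"
            )


def validate_schema(schema: Sequence[VariableSchema]) -> None:
    """Check the cross-variable invariants of a schema set.

    Exactly one exposure and one outcome must be present; the outcome must
    be binary and the exposure continuous; names must be unique.
    """
    names = [v.name for v in schema]
    if len(set(names)) != len(names):
        raise SchemaError("duplicate variable names in schema")
    exposures = [v for v in schema if v.role == "exposure"]
    outcomes = [v for v in schema if v.role == "outcome"]
    if len(exposures) != 1:
        raise SchemaError(f"schema must have exactly one exposure, got {len(exposures)}")
    if len(outcomes) != 1:
        raise SchemaError(f"schema must have exactly one outcome, got {len(outcomes)}")
    if exposures[0].kind != "continuous":
        raise SchemaError("exposure must be continuous")
    if outcomes[0].kind != "binary":
        raise SchemaError("outcome must be binary")


def exposure_name(schema: Sequence[VariableSchema]) -> str:
    return next(v.name for v in schema if v.role == "exposure")


def outcome_name(schema: Sequence[VariableSchema]) -> str:
    return next(v.name for v in schema if v.role == "outcome")


def by_name(schema: Sequence[VariableSchema], name: str) -> VariableSchema:
    for v in schema:
        if v.name == name:
            return v
    raise SchemaError(f"variable {name!r} not in schema")


def covariate_names(schema: Sequence[VariableSchema]) -> list[str]:
    return [v.name for v in schema if v.role in ("covariate", "stratifier")]


def default_schema() -> list[VariableSchema]:
    """Schema of the elderly-sepsis cohort table.

    The mean_sd vs median_iqr assignment mirrors the conventional baseline
    table for this cohort: WBC, BUN, SOFA (right-skewed) use median (IQR);
    the other continuous covariates use mean +/- SD.
    """
    V = VariableSchema
    return [
        V("lactate", "exposure", "continuous", "mmol/L", "median_iqr"),
        V("mortality_28d", "outcome", "binary", "", "count_pct"),
        V("age", "covariate", "continuous", "years", "mean_sd"),
        V("gender", "covariate", "binary", "", "count_pct"),
        V("copd", "covariate", "binary", "", "count_pct"),
        V("chf", "covariate", "binary", "", "count_pct"),
        V("ami", "covariate", "binary", "", "count_pct"),
        V("dm", "covariate", "binary", "", "count_pct"),
        V("hr", "covariate", "continuous", "beats/min", "mean_sd"),
        V("temperature", "covariate", "continuous", "degC", "mean_sd"),
        V("hemoglobin", "covariate", "continuous", "g/dL", "mean_sd"),
        V("potassium", "covariate", "continuous", "mmol/L", "mean_sd"),
        V("rbc", "covariate", "continuous", "M/mcL", "mean_sd"),
        V("sodium", "covariate", "continuous", "mmol/L", "mean_sd"),
        V("wbc", "covariate", "continuous", "1e9/L", "median_iqr"),
        V("bicarbonate", "covariate", "continuous", "mmol/L", "mean_sd"),
        V("rdw", "covariate", "continuous", "%", "mean_sd"),
        V("bun", "covariate", "continuous", "mg/dL", "median_iqr"),
        V("apache_iv", "covariate", "continuous", "", "mean_sd"),
        V("sofa", "stratifier", "continuous", "", "median_iqr"),
        V("unit_type", "covariate", "categorical", "", "count_pct"),
        V("icu_los_hours", "admin", "continuous", "hours", "median_iqr"),
        V("sepsis", "admin", "binary", "", "count_pct"),
        V("lactate_count", "admin", "continuous", "", "median_iqr"),
        V("time_to_death_hours", "admin", "continuous", "hours", "median_iqr"),
    ]


def load_schema(path: str | Path) -> list[VariableSchema]:
    """Read a schema from a JSON or YAML file (list of variable mappings)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, list):
        raise SchemaError("schema file must contain a list of variable mappings")
    schema = [VariableSchema(**entry) for entry in raw]
    validate_schema(schema)
    return schema


def save_schema(schema: Iterable[VariableSchema], path: str | Path) -> None:
    rows = [vars(v).copy() for v in schema]
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(rows, indent=1))
    else:
        path.write_text(yaml.safe_dump(rows, sort_keys=False))
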
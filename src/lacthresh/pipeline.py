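"""End-to-end run orchestration and report-bundle assembly.

``run_pipeline`` executes the full analysis in the conventional order —
filter, impute, quartile-bin, baseline table, crude/adjusted effect
models, smooth curves, threshold search with bootstrap, subgroups — and
writes a self-describing bundle: TSV tables mirroring the report layouts,
per-curve CSVs, and a JSON manifest with per-stage row counts, seeds and
output checksums. Stages fail independently: an error in one stage is
recorded in the manifest and unrelated stages still run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import schema as sc
from ._format import format_or, format_p
from .cohort import (
    CohortTable, ExclusionCriteria, apply_exclusions, impute_median,
    quartile_bin, read_cohort, write_cohort,
)
from .descriptives import baseline_frame, baseline_table
from .effects import (
    MODEL_II_COVARIATES, ModelSpec, effect_table, fit_logistic, proportion_ci,
)
from .errors import ConfigError, LacthreshError
from .simulate import GeneratedCohort, SyntheticConfig, default_config, generate_cohort
from .smooth import fit_smooth, sofa_rule, stratified_smooth
from .subgroups import forest_frame, subgroup_effects
from .threshold import (
    BootstrapSettings, bootstrap_turning_point, find_turning_point, make_grid,
)

log = logging.getLogger(__name__)

DEFAULT_SUBGROUPS = ("hr", "temperature", "potassium", "wbc", "bicarbonate",
                     "rdw", "bun", "apache_iv", "sofa")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_path`` (cohort CSV) or ``simulate``
    (:class:`~lacthresh.simulate.SyntheticConfig`) must be given. ``seed``
    is required whenever any stochastic stage (simulation, bootstrap) is
    enabled.
    """

    input_path: str | None = None
    simulate: SyntheticConfig | None = None
    schema_path: str | None = None
    outdir: str = "lacthresh_run"
    seed: int | None = None
    apply_exclusion_filters: bool = True
    grid_low_pct: float = 5.0
    grid_high_pct: float = 95.0
    grid_step: float = 0.1
    bootstrap_replicates: int = 500
    spline_df: int = 4
    sofa_cut: float = 5.0
    subgroups: tuple[str, ...] = DEFAULT_SUBGROUPS
    covariates: tuple[str, ...] = MODEL_II_COVARIATES

    def validate(self) -> "RunConfig":
        if (self.input_path is None) == (self.simulate is None):
            raise ConfigError("exactly one of input_path / simulate must be set")
        stochastic = self.simulate is not None or self.bootstrap_replicates > 0
        if stochastic and self.seed is None:
            raise ConfigError("seed is required when simulation or bootstrap is enabled")
        if self.grid_step <= 0:
            raise ConfigError("grid step must be positive")
        return self


def config_from_yaml(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sim = raw.pop("simulate", None)
    cfg = RunConfig(**{k: tuple(v) if isinstance(v, list) else v
                       for k, v in raw.items()})
    if sim is not None:
        base = default_config(**{k: v for k, v in sim.items()})
        cfg.simulate = base
        if cfg.seed is None:
            cfg.seed = base.seed
    return cfg.validate()


@dataclass
class ReportBundle:
    """In-memory results of a run plus the path of its written bundle."""

    outdir: Path
    cohort: CohortTable
    manifest: dict
    threshold: object | None = None
    effects: dict = field(default_factory=dict)
    table1: pd.DataFrame | None = None
    curves: list = field(default_factory=list)
    subgroups: pd.DataFrame | None = None


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _effects_rows(t: CohortTable, labels, exposure_form: str,
                  models: Sequence[ModelSpec]) -> list[dict]:
    rows = []
    for spec in models:
        fit = fit_logistic(t, dataclasses.replace(spec, exposure=exposure_form),
                           quartile_labels=labels)
        wanted = [tm for tm in fit.terms if tm.startswith(t.exposure)]
        for e in effect_table(fit, wanted):
            rows.append({"model": spec.name, "term": e.term,
                         "or": round(e.odds_ratio, 6),
                         "ci_low": round(e.ci_low, 6),
                         "ci_high": round(e.ci_high, 6),
                         "p_value": e.p_value,
                         "display": f"{format_or(e.odds_ratio, e.ci_low, e.ci_high)}"
                                    f"  {format_p(e.p_value)}"})
    return rows


def _load_cohort(cfg: RunConfig) -> tuple[CohortTable, dict]:
    if cfg.simulate is not None:
        sim_cfg = cfg.simulate
        if cfg.seed is not None and sim_cfg.seed != cfg.seed:
            sim_cfg = dataclasses.replace(sim_cfg, seed=cfg.seed)
        gen = generate_cohort(sim_cfg)
        return gen.table, {"source": "simulate", "realized": gen.realized}
    schema = sc.load_schema(cfg.schema_path) if cfg.schema_path else None
    t = read_cohort(cfg.input_path, schema)
    return t, {"source": cfg.input_path}


def run_pipeline(cfg: RunConfig) -> ReportBundle:
    """Execute every analysis stage and write the report bundle."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "curves").mkdir(exist_ok=True)
    manifest: dict = {"package": "lacthresh", "version": __version__,
                      "seed": cfg.seed, "stages": {}, "errors": {}, "outputs": {}}

    t, src_info = _load_cohort(cfg)
    manifest["stages"]["load"] = {"rows": t.n, **src_info}

    if cfg.apply_exclusion_filters:
        t, removed = apply_exclusions(t)
        manifest["stages"]["exclusions"] = {"rows": t.n, "removed": removed}
        (outdir / "exclusions.json").write_text(json.dumps(removed, indent=1))
    t = impute_median(t)
    manifest["stages"]["impute"] = {"rows": t.n}
    write_cohort(t, outdir / "cohort.csv")

    binning, labels = quartile_bin(t)
    manifest["stages"]["quartiles"] = {
        "rows": t.n, "cutpoints": list(binning.cutpoints)}

    bundle = ReportBundle(outdir=outdir, cohort=t, manifest=manifest)

    def stage(name, fn):
        try:
            fn()
            manifest["stages"].setdefault(name, {}).setdefault("rows", t.n)
        except LacthreshError as e:
            log.warning("stage %s failed: %s", name, e)
            manifest["errors"][name] = str(e)

    def _table1():
        rows = baseline_table(t, labels)
        frame = baseline_frame(rows)
        frame.to_csv(outdir / "table1.tsv", sep="\t", index=False)
        bundle.table1 = frame

    def _mortality():
        y = t.df[t.outcome]
        p, lo, hi = proportion_ci(int(y.sum()), int(y.notna().sum()))
        manifest["stages"]["mortality"] = {
            "rows": t.n, "rate_pct": round(100 * p, 2),
            "ci_pct": [round(100 * lo, 2), round(100 * hi, 2)]}

    def _effects():
        models = [ModelSpec.crude(), ModelSpec.model_i(), ModelSpec.model_ii()]
        rows = (_effects_rows(t, labels, "linear", models)
                + _effects_rows(t, labels, "quartiles", models))
        frame = pd.DataFrame(rows)
        frame[["model", "term", "display"]].to_csv(
            outdir / "effects.tsv", sep="\t", index=False)
        (outdir / "effects.json").write_text(
            json.dumps(rows, indent=1, default=float))
        bundle.effects = {"rows": rows}

    def _threshold():
        grid = make_grid(t, cfg.grid_low_pct, cfg.grid_high_pct, cfg.grid_step)
        pw = find_turning_point(t, grid, cfg.covariates)
        if cfg.bootstrap_replicates > 0:
            settings = BootstrapSettings(cfg.bootstrap_replicates, seed=cfg.seed)
            pw.K_ci, _, n_failed = bootstrap_turning_point(
                t, grid, cfg.covariates, settings)
            manifest["stages"]["bootstrap"] = {
                "replicates": cfg.bootstrap_replicates, "failed": n_failed}
        rows = [
            {"row": "one_line_or",
             "value": format_or(*_one_line(t, cfg.covariates)),
             "p": ""},
            {"row": "turning_point_K", "value": f"{pw.K:.1f}",
             "p": "" if pw.K_ci is None else
             f"95% CI ({pw.K_ci[0]:.1f}, {pw.K_ci[1]:.1f})"},
            {"row": "exposure_below_K",
             "value": format_or(pw.or_below.odds_ratio, pw.or_below.ci_low,
                                pw.or_below.ci_high),
             "p": format_p(pw.or_below.p_value)},
            {"row": "exposure_at_or_above_K",
             "value": format_or(pw.or_above.odds_ratio, pw.or_above.ci_low,
                                pw.or_above.ci_high),
             "p": format_p(pw.or_above.p_value)},
            {"row": "lrt_linear_vs_piecewise", "value": f"{pw.lrt_statistic:.3f}",
             "p": format_p(pw.lrt_p)},
        ]
        pd.DataFrame(rows).to_csv(outdir / "threshold.tsv", sep="\t", index=False)
        (outdir / "threshold_profile.json").write_text(json.dumps(
            {"K": pw.K, "loglik_piecewise": pw.loglik_piecewise,
             "loglik_linear": pw.loglik_linear, "lrt_p": pw.lrt_p,
             "K_ci": pw.K_ci,
             "profile": pw.profile.to_dict(orient="list")}, indent=1))
        bundle.threshold = pw
        manifest["stages"]["threshold"] = {
            "rows": pw.fit.n_used, "K": pw.K,
            "skipped_candidates": len(pw.skipped_candidates)}

    def _curves():
        overall = fit_smooth(t, cfg.covariates, spline_df=cfg.spline_df)
        overall.to_frame().to_csv(outdir / "curves" / "overall.csv", index=False)
        bundle.curves = [overall]
        for c in stratified_smooth(t, sofa_rule(cfg.sofa_cut), cfg.covariates,
                                   spline_df=cfg.spline_df):
            safe = c.stratum.replace("<=", "le").replace(">", "gt")
            c.to_frame().to_csv(outdir / "curves" / f"{safe}.csv", index=False)
            bundle.curves.append(c)

    def _subgroups():
        res = subgroup_effects(t, cfg.subgroups, cfg.covariates)
        frame = forest_frame(res)
        frame.to_csv(outdir / "subgroups.tsv", sep="\t", index=False)
        bundle.subgroups = frame

    stage("table1", _table1)
    stage("mortality", _mortality)
    stage("effects", _effects)
    stage("threshold", _threshold)
    stage("curves", _curves)
    stage("subgroups", _subgroups)

    for f in sorted(outdir.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["outputs"][str(f.relative_to(outdir))] = _sha256(f)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                     default=float))
    return bundle


def _one_line(t: CohortTable, covariates) -> tuple[float, float, float]:
    spec = ModelSpec(exposure="linear", covariates=tuple(covariates), name="one_line")
    e = effect_table(fit_logistic(t, spec), [t.exposure])[0]
    return e.odds_ratio, e.ci_low, e.ci_high


VARIANTS = ("complete_case", "drop_first_24h_deaths")


def sensitivity_run(cfg: RunConfig, variant: str,
                    main: ReportBundle | None = None) -> ReportBundle:
    """Re-run the pipeline on a sensitivity-variant cohort.

    ``complete_case`` drops rows with any missing covariate instead of
    imputing; ``drop_first_24h_deaths`` removes patients who died within
    24 h of admission (requires a time-to-death column). The bundle gains a
    ``sensitivity.json`` with side-by-side deltas against the main run.
    """
    if variant not in VARIANTS:
        raise ConfigError(f"unknown sensitivity variant {variant!r}")
    cfg.validate()
    if main is None:
        main = run_pipeline(cfg)
    t = main.cohort  # already filtered/imputed
    t_raw, _ = _load_cohort(cfg)
    if cfg.apply_exclusion_filters:
        t_raw, _ = apply_exclusions(t_raw)

    if variant == "complete_case":
        covs = [v.name for v in t_raw.schema
                if v.role in ("covariate", "stratifier") and v.name in t_raw.df.columns]
        keep = t_raw.df[covs].notna().all(axis=1)
        t_var = CohortTable(t_raw.df[keep].reset_index(drop=True), t_raw.schema)
    else:
        col = "time_to_death_hours"
        if col not in t_raw.df.columns:
            raise ConfigError(f"variant {variant!r} requires column {col!r}")
        died_early = (t_raw.df[t_raw.outcome] == 1) & (t_raw.df[col] < 24.0)
        t_var = impute_median(CohortTable(t_raw.df[~died_early].reset_index(drop=True),
                                          t_raw.schema))

    sub = dataclasses.replace(
        cfg, outdir=str(Path(cfg.outdir) / f"sensitivity_{variant}"),
        apply_exclusion_filters=False)
    # run on the pre-built variant table by writing it as the input
    var_path = Path(sub.outdir)
    var_path.mkdir(parents=True, exist_ok=True)
    write_cohort(t_var, var_path / "_variant_input.csv")
    sub = dataclasses.replace(sub, input_path=str(var_path / "_variant_input.csv"),
                              simulate=None)
    bundle = run_pipeline(sub)

    deltas = {"variant": variant, "n_main": main.cohort.n, "n_variant": t_var.n}
    if main.threshold is not None and bundle.threshold is not None:
        deltas["K_main"] = main.threshold.K
        deltas["K_variant"] = bundle.threshold.K
        deltas["K_delta"] = bundle.threshold.K - main.threshold.K
        for side in ("or_below", "or_above"):
            m = getattr(main.threshold, side).odds_ratio
            v = getattr(bundle.threshold, side).odds_ratio
            deltas[f"{side}_main"] = m
            deltas[f"{side}_variant"] = v
            deltas[f"{side}_delta"] = v - m
    (Path(sub.outdir) / "sensitivity.json").write_text(
        json.dumps(deltas, indent=1, default=float))
    bundle.manifest["sensitivity"] = deltas
    return bundle
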
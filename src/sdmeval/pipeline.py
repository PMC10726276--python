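"""End-to-end evaluation grid: model variants x strategies x levels x metrics.

Given a community (real, read from CSV, or synthetic), this module fits every
requested model variant, produces predictions under every evaluation strategy,
aggregates observations and probabilities to every hierarchical level, scores
the four discrimination metrics per species, and emits one long-form table —
one row per species x variant x strategy x level x metric — plus a JSON
manifest capturing seeds and configuration for reproducibility.

Input CSV schemas (also what the synthetic generator writes):

* occurrences: ``unit_id`` plus one 0/1 column per species;
* covariates:  ``unit_id, plot_id, site_id, management, volume, decay``.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .crossval import STRATEGIES, FitLog, explanatory_predictions, make_folds, repeat_cv
from .hierarchy import LEVELS, HierarchicalDesign, aggregate_matrix
from .metrics import METRIC_NAMES, PredictionSet, evaluate_all, transform_auc, transform_tjur
from .probit import SamplerSettings, VARIANTS
from .simulate import CommunityData, SyntheticConfig, simulate_community

__all__ = [
    "PipelineConfig",
    "EvaluationResult",
    "run_grid",
    "evaluate_predictions",
    "read_community_csv",
    "write_results",
]

COVARIATE_COLUMNS = ("unit_id", "plot_id", "site_id", "management", "volume", "decay")


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one evaluation run.

    Defaults follow the study design this package emulates: three model
    variants, four evaluation strategies, three levels, five folds repeated
    ten times, and a ten-occurrence species floor.
    """

    synthetic: SyntheticConfig | None = None
    occurrence_path: str | None = None
    covariate_path: str | None = None
    variants: tuple[str, ...] = VARIANTS
    strategies: tuple[str, ...] = STRATEGIES
    levels: tuple[str, ...] = LEVELS
    k: int = 5
    n_repeats: int = 10
    min_occurrences: int = 10
    tie_policy: str = "half"
    repeat_aggregation: str = "metric_mean"  # or "prediction_mean"
    sampler: SamplerSettings = field(default_factory=SamplerSettings)
    seed: int = 0

    def __post_init__(self) -> None:
        for v in self.variants:
            if v not in VARIANTS:
                raise ValueError(f"unknown variant {v!r}")
        for s in self.strategies:
            if s not in STRATEGIES:
                raise ValueError(f"unknown strategy {s!r}")
        for lv in self.levels:
            if lv not in LEVELS:
                raise ValueError(f"unknown level {lv!r}")
        if self.repeat_aggregation not in ("metric_mean", "prediction_mean"):
            raise ValueError("repeat_aggregation must be 'metric_mean' or 'prediction_mean'")


@dataclass
class EvaluationResult:
    """Long-form metric table plus run provenance."""

    table: pd.DataFrame
    manifest: dict
    fit_log: FitLog
    fold_frames: dict[str, pd.DataFrame] = field(default_factory=dict)


def read_community_csv(occurrence_path: str | Path, covariate_path: str | Path) -> CommunityData:
    """Read and validate the occurrence/covariate CSV pair.

    Rows are aligned by ``unit_id``; duplicate ids, non-binary occurrence
    entries, missing covariates and unmatched ids are rejected with the
    offenders named.
    """
    occ = pd.read_csv(occurrence_path)
    cov = pd.read_csv(covariate_path)
    if "unit_id" not in occ.columns:
        raise ValueError(f"{occurrence_path}: missing 'unit_id' column")
    missing_cols = [c for c in COVARIATE_COLUMNS if c not in cov.columns]
    if missing_cols:
        raise ValueError(f"{covariate_path}: missing columns {missing_cols}")
    for name, frame in (("occurrence", occ), ("covariate", cov)):
        dup = frame["unit_id"][frame["unit_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate unit_id in {name} table: {dup.iloc[0]!r}")
    if set(occ["unit_id"]) != set(cov["unit_id"]):
        odd = set(occ["unit_id"]).symmetric_difference(cov["unit_id"])
        raise ValueError(f"unit_id mismatch between tables, e.g. {sorted(odd)[:5]}")
    if cov[list(COVARIATE_COLUMNS)].isna().any().any():
        bad = cov[list(COVARIATE_COLUMNS)].isna().any()
        raise ValueError(f"missing covariate values in columns {list(bad[bad].index)}")
    occ = occ.set_index("unit_id").loc[cov["unit_id"]].reset_index()
    species = [c for c in occ.columns if c != "unit_id"]
    mat = occ[species].to_numpy()
    bad_rows = np.flatnonzero(~np.isin(mat, (0, 1)).all(axis=1))
    if len(bad_rows):
        raise ValueError(
            f"non-binary occurrence entries at rows {bad_rows[:5].tolist()} "
            f"(unit_id {occ['unit_id'].iloc[bad_rows[0]]!r})")
    mgmt = cov.groupby("site_id")["management"].nunique()
    if (mgmt > 1).any():
        raise ValueError(f"management varies within site {mgmt[mgmt > 1].index[0]!r}")
    design = HierarchicalDesign.from_frame(cov)
    return CommunityData(design=design, covariates=cov, occurrences=occ[species])


def _metric_row(species: str, variant: str, strategy: str, level: str,
                metric: str, raw: float, n1: float, n0: float, used: int) -> dict:
    transformed = raw
    if metric == "auc":
        transformed = transform_auc(raw)
    elif metric == "tjur_r2":
        transformed = transform_tjur(raw)
    return {
        "species": species, "model_variant": variant, "strategy": strategy,
        "level": level, "metric": metric, "raw_value": raw,
        "transformed_value": transformed, "n_presences": n1, "n_absences": n0,
        "n_repeats_used": used, "missing_flag": bool(np.isnan(raw)),
    }


def _score_matrix(y_agg: np.ndarray, p_agg: np.ndarray, species: list[str],
                  tie_policy: str) -> dict[str, dict[str, float]]:
    """Per-species metric dict at one level, honouring NaN predictions."""
    out: dict[str, dict[str, float]] = {}
    for j, name in enumerate(species):
        p = p_agg[:, j]
        ok = ~np.isnan(p)
        y = y_agg[ok, j]
        rec = {m: np.nan for m in METRIC_NAMES}
        rec["n_presences"] = float(y.sum())
        rec["n_absences"] = float(ok.sum() - y.sum())
        if ok.any() and 0 < y.sum() < ok.sum():
            ms = evaluate_all(PredictionSet(y, p[ok]), tie_policy=tie_policy)
            rec.update({m: getattr(ms, m) for m in METRIC_NAMES})
        out[name] = rec
    return out


def evaluate_predictions(data: CommunityData, pred_repeats: list[pd.DataFrame],
                         variant: str, strategy: str,
                         levels=LEVELS, tie_policy: str = "half",
                         repeat_aggregation: str = "metric_mean") -> list[dict]:
    """Score one variant x strategy cell of the grid at every requested level.

    ``metric_mean`` computes the metrics per CV repeat and averages the
    values over repeats where defined; ``prediction_mean`` first averages the
    repeat prediction matrices and scores once.
    """
    y_unit = data.occurrence_matrix().astype(float)
    species = data.species
    if repeat_aggregation == "prediction_mean" and len(pred_repeats) > 1:
        pred_repeats = [pd.DataFrame(
            np.nanmean(np.stack([p.to_numpy() for p in pred_repeats]), axis=0),
            columns=species)]
    rows: list[dict] = []
    for level in levels:
        y_agg = aggregate_matrix(y_unit, data.design, level, kind="occurrence")
        per_repeat = []
        for preds in pred_repeats:
            p_agg = aggregate_matrix(preds.to_numpy(), data.design, level)
            per_repeat.append(_score_matrix(y_agg, p_agg, species, tie_policy))
        for name in species:
            recs = [r[name] for r in per_repeat]
            n1 = recs[0]["n_presences"]
            n0 = recs[0]["n_absences"]
            for metric in METRIC_NAMES:
                vals = np.array([r[metric] for r in recs])
                used = int(np.sum(~np.isnan(vals)))
                raw = float(np.nanmean(vals)) if used else float("nan")
                rows.append(_metric_row(name, variant, strategy, level, metric,
                                        raw, n1, n0, used))
    return rows


def _load_data(config: PipelineConfig) -> CommunityData:
    if config.synthetic is not None:
        synth = config.synthetic
        if synth.seed != config.seed:
            synth = SyntheticConfig(**{**asdict(synth), "seed": config.seed})
        return simulate_community(synth)
    if not (config.occurrence_path and config.covariate_path):
        raise ValueError("provide either a synthetic config or both CSV paths")
    data = read_community_csv(config.occurrence_path, config.covariate_path)
    keep = data.occurrences.sum(axis=0) >= config.min_occurrences
    return CommunityData(design=data.design, covariates=data.covariates,
                         occurrences=data.occurrences.loc[:, keep])


def run_grid(config: PipelineConfig, data: CommunityData | None = None) -> EvaluationResult:
    """Run the full evaluation grid and return the long-form result table."""
    if data is None:
        data = _load_data(config)
    log = FitLog()
    sampler = config.sampler.with_seed(config.seed)
    rows: list[dict] = []
    fold_frames: dict[str, pd.DataFrame] = {}
    for strategy in config.strategies:
        if strategy != "explanatory":
            level = strategy.removeprefix("cv_")
            for r in range(config.n_repeats):
                folds = make_folds(data.design, level, k=config.k,
                                   seed=config.seed, repeat_index=r)
                fold_frames[f"folds_{strategy}_{r}"] = folds.to_frame(data.design)
    for variant in config.variants:
        for strategy in config.strategies:
            if strategy == "explanatory":
                preds = [explanatory_predictions(data, variant, sampler, log=log)]
            else:
                level = strategy.removeprefix("cv_")
                preds = repeat_cv(data, variant, level, k=config.k,
                                  n_repeats=config.n_repeats,
                                  base_seed=config.seed, sampler=sampler, log=log)
            rows.extend(evaluate_predictions(
                data, preds, variant, strategy, levels=config.levels,
                tie_policy=config.tie_policy,
                repeat_aggregation=config.repeat_aggregation))
    table = pd.DataFrame(rows)
    manifest = {
        "package": "sdmeval",
        "version": __version__,
        "seed": config.seed,
        "config": _manifest_config(config),
        "n_species": len(data.species),
        "n_units": data.n_units,
        "n_plots": data.design.n_plots,
        "n_sites": data.design.n_sites,
        "skipped_fits": log.skipped,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    return EvaluationResult(table=table, manifest=manifest, fit_log=log,
                            fold_frames=fold_frames)


def _manifest_config(config: PipelineConfig) -> dict:
    out = asdict(config)
    return json.loads(json.dumps(out, default=str))


def write_results(result: EvaluationResult, out_dir: str | Path) -> dict[str, Path]:
    """Write ``results.csv`` and ``manifest.json`` to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    csv_path = out / "results.csv"
    result.table.to_csv(csv_path, index=False)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(result.manifest, indent=2))
    paths = {"results": csv_path, "manifest": manifest_path}
    for name, frame in result.fold_frames.items():
        fold_path = out / f"{name}.csv"
        frame.to_csv(fold_path, index=False)
        paths[name] = fold_path
    return paths
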
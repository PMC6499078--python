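"""End-to-end pipeline: decompose -> label -> compare -> map.

Configuration lives in a small versioned YAML schema; every run writes a
machine-readable JSON summary carrying full provenance (seed, package
version, config hash) so any run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (
    fit_shared_regression,
    fit_unshared_regression,
    pairwise_stats,
    run_suma,
    solve_components,
    stratified_suma,
    summarize_predictions,
)
from .io import SampleSpec, read_ensemble_table, read_meta, subsample
from .labels import compare_groups, dichotomize, mean_covariances, tabulate_labels
from .spatial import (
    CovariateSpec,
    covariate_odds_ratios,
    fit_gam,
    predict_surface,
    surface_to_geojson,
)

__all__ = ["RunConfig", "ConfigError", "validate_config", "run_full_pipeline"]

log = logging.getLogger("sumaerr")

CONFIG_SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Raised with the full list of configuration problems."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(errors))


@dataclass
class RunConfig:
    ensembles: Path
    meta: Path
    out_dir: Path
    sample_size: int = 2500
    n_repeats: int = 11
    seed: int = 0
    percentile: float = 80.0
    strata: str | None = None  # metadata column for the stratified analysis
    compare_variables: list[str] = field(default_factory=list)
    tabulate_by: list[str] = field(default_factory=list)
    covariates: list[CovariateSpec] = field(default_factory=list)
    n_grid: int = 50
    alpha: float = 5e-7
    backend: str = "spline"

    def sample_spec(self) -> SampleSpec:
        return SampleSpec(sample_size=self.sample_size, n_repeats=self.n_repeats, seed=self.seed)


def validate_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration, collecting all errors."""
    raw = yaml.safe_load(Path(path).read_text())
    errors: list[str] = []
    if not isinstance(raw, dict):
        raise ConfigError(["configuration must be a YAML mapping"])
    if raw.get("schema_version", CONFIG_SCHEMA_VERSION) != CONFIG_SCHEMA_VERSION:
        errors.append(f"unsupported schema_version {raw.get('schema_version')!r}")

    def need_path(key: str) -> Path | None:
        v = raw.get(key)
        if v is None:
            errors.append(f"missing required field {key!r}")
            return None
        p = Path(v)
        if not p.exists():
            errors.append(f"{key}: file {p} does not exist")
        return p

    ensembles = need_path("ensembles")
    meta = need_path("meta")
    out_dir = Path(raw.get("out_dir", "suma_out"))

    def num(key, default, lo=None, hi=None, kind=float):
        v = raw.get(key, default)
        try:
            v = kind(v)
        except (TypeError, ValueError):
            errors.append(f"{key}: expected a number, got {v!r}")
            return default
        if lo is not None and not (lo < v):
            errors.append(f"{key} must be > {lo}")
        if hi is not None and not (v < hi):
            errors.append(f"{key} must be < {hi}")
        return v

    sample_size = num("sample_size", 2500, lo=0, kind=int)
    n_repeats = num("n_repeats", 11, lo=0, kind=int)
    seed = num("seed", 0, kind=int)
    percentile = num("percentile", 80.0, lo=0, hi=100)
    alpha = num("alpha", 5e-7, lo=0, hi=1)
    n_grid = num("n_grid", 50, lo=1, kind=int)
    backend = raw.get("backend", "spline")
    if backend not in ("spline", "loess"):
        errors.append(f"backend must be spline|loess, got {backend!r}")

    covariates = []
    for item in raw.get("covariates", []) or []:
        if isinstance(item, str):
            covariates.append(CovariateSpec(item))
        elif isinstance(item, dict) and "name" in item:
            try:
                covariates.append(
                    CovariateSpec(
                        name=item["name"],
                        kind=item.get("kind", "continuous"),
                        iqr=item.get("iqr"),
                        reference=item.get("reference"),
                    )
                )
            except ValueError as e:
                errors.append(str(e))
        else:
            errors.append(f"covariates entries must be names or mappings with a 'name', got {item!r}")

    if errors:
        raise ConfigError(errors)
    return RunConfig(
        ensembles=ensembles,
        meta=meta,
        out_dir=out_dir,
        sample_size=sample_size,
        n_repeats=n_repeats,
        seed=seed,
        percentile=percentile,
        strata=raw.get("strata"),
        compare_variables=list(raw.get("compare_variables", []) or []),
        tabulate_by=list(raw.get("tabulate_by", []) or []),
        covariates=covariates,
        n_grid=n_grid,
        alpha=alpha,
        backend=backend,
    )


def _config_hash(config: RunConfig) -> str:
    payload = {k: str(v) for k, v in config.__dict__.items()}
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def run_full_pipeline(config: RunConfig) -> dict:
    """Execute the whole analysis and write the report bundle.

    Stages: decompose (SUMA components, per-repeat robustness, optional
    strata), label (mean covariances, high/low dichotomization), compare
    (group tests and tabulations), map (spatial GAM, surface, covariate
    odds ratios).  Outputs CSV tables, a GeoJSON surface, and
    ``summary.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "provenance": {
            "package_version": __version__,
            "seed": config.seed,
            "config_hash": _config_hash(config),
            "config": {k: str(v) for k, v in config.__dict__.items()},
        }
    }
    stage = "decompose"
    try:
        t0 = time.time()
        table = read_ensemble_table(config.ensembles)
        meta = read_meta(config.meta)
        log.info("loaded %d predictions x %d replicates", table.n_pred, table.n_ens)
        spec = config.sample_spec()
        result = run_suma(table, meta, spec)
        summary["suma"] = {
            "components": result.components.to_dict(),
            "per_repeat": result.summary.to_dict(orient="records"),
            "spread": result.spread().to_dict(),
        }
        result.summary.to_csv(out / "components_per_repeat.csv", index=False)
        if config.strata:
            strat = stratified_suma(table, meta, config.strata, spec)
            summary["stratified"] = {
                k: {"components": v["components"].to_dict(), "pair_summary": v["pair_summary"], "n": v["n"]}
                for k, v in strat.items()
            }
        log.info("decompose done in %.1fs", time.time() - t0)

        stage = "label"
        t0 = time.time()
        sub, sub_meta = subsample(table, meta, SampleSpec(config.sample_size, 1, config.seed))[0]
        pairs = pairwise_stats(sub)
        mc = mean_covariances(pairs, n_pred=sub.n_pred)
        labels = dichotomize(mc, percentile=config.percentile, prediction_ids=sub.prediction_ids)
        labels.frame.to_csv(out / "labels.csv", index=False)
        summary["labels"] = {
            "n": int(len(labels.frame)),
            "n_high": labels.n_high,
            "threshold": labels.threshold,
            "percentile": labels.percentile,
        }
        log.info("label done in %.1fs (%d high)", time.time() - t0, labels.n_high)

        stage = "compare"
        t0 = time.time()
        if config.compare_variables:
            comp = compare_groups(labels, sub_meta, config.compare_variables)
            comp.to_csv(out / "group_comparison.csv", index=False)
            summary["comparison"] = comp.to_dict(orient="records")
        tabs = {}
        for by in config.tabulate_by:
            tab = tabulate_labels(labels, sub_meta, by)
            tab.to_csv(out / f"tabulation_{by}.csv", index=False)
            tabs[by] = tab.to_dict(orient="records")
        if tabs:
            summary["tabulations"] = tabs
        log.info("compare done in %.1fs", time.time() - t0)

        stage = "map"
        t0 = time.time()
        model = fit_gam(labels, sub_meta, config.covariates, backend=config.backend)
        surface = predict_surface(model, n_grid=config.n_grid, alpha=config.alpha)
        surface_to_geojson(surface, out / "surface.geojson")
        ors = covariate_odds_ratios(model) if config.covariates else pd.DataFrame()
        if len(ors):
            ors.to_csv(out / "covariate_odds_ratios.csv", index=False)
        summary["map"] = {
            "smooth_p": model.smooth_p,
            "edf": model.edf,
            "deviance": model.deviance,
            "or_range": list(surface.or_range),
            "flagged_fraction": surface.flagged_fraction,
            "n_grid_points": int(len(surface.grid)),
            "odds_ratios": ors.to_dict(orient="records") if len(ors) else [],
        }
        log.info("map done in %.1fs", time.time() - t0)
    except Exception as e:
        log.error("pipeline stage %r failed: %s", stage, e)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=_jsonable))
    return summary


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (pd.Timestamp,)):
        return obj.isoformat()
    return str(obj)
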
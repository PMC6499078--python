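"""Spatial mapping of high shared multiplicative measurement error.

Fits the logistic GAM  logit p(x, y) = s(x, y) + gamma' * covariates  for
the odds that a prediction carries a high-SMME label (low is the
reference), predicts odds ratios over an evenly spaced grid clipped to the
convex hull of the observation locations, and flags grid points whose
pointwise confidence band excludes odds ratio 1 at a (very strict) alpha.

The mapped odds ratio at a grid point is relative to the sample-average
predicted log-odds: the smooth term is centered over the sample, so
``OR(g) = exp(s(g))``.  Covariate terms therefore cancel out of the map and
enter only through their fitted coefficients (reported per interquartile
range for continuous covariates).

Covariate selection mirrors an iterative build: candidates are added one
at a time to the current model and retained when they move the surface's
odds-ratio range (max - min, or either endpoint) by at least 10% relative
to the model without them.  Whether a candidate "alters the spatial
pattern" is inherently a judgment call, so it is quantified (Jaccard
overlap of flagged areas before/after) and reported for human review
rather than auto-decided.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from scipy import stats
from shapely.geometry import MultiPoint

from .gam import LoessLogisticGAM, SplineLogisticGAM
from .labels import SmmeLabelSet

__all__ = [
    "CovariateSpec",
    "GamModel",
    "GamSurface",
    "fit_gam",
    "predict_surface",
    "iterative_covariate_selection",
    "covariate_odds_ratios",
    "surface_to_geojson",
]

DEFAULT_ALPHA = 5e-7


@dataclass
class CovariateSpec:
    """A covariate entering the GAM's parametric part.

    Continuous covariates report odds ratios per ``iqr`` increase (computed
    from the data when not given); categorical covariates are dummy-coded
    against ``reference`` (their first observed level when not given).
    """

    name: str
    kind: str = "continuous"  # or "categorical"
    iqr: float | None = None
    reference: object | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"covariate kind must be continuous|categorical, got {self.kind!r}")
        if self.iqr is not None and self.iqr <= 0:
            raise ValueError(f"IQR for {self.name!r} must be > 0")


@dataclass
class GamModel:
    """A fitted spatial logistic GAM plus the bookkeeping to report it."""

    backend: SplineLogisticGAM | LoessLogisticGAM
    covariates: list[CovariateSpec]
    column_names: list[str]  # parametric design column names (incl. intercept)
    column_map: dict[str, list[int]]  # covariate name -> design column indices
    coords: np.ndarray
    deviance: float
    edf: float
    smooth_p: float

    @property
    def fitted(self) -> np.ndarray:
        return self.backend.mu_


@dataclass
class GamSurface:
    """Gridded odds-ratio surface with pointwise significance flags."""

    grid: pd.DataFrame  # x, y, log_or, se, odds_ratio, flag
    alpha: float
    spacing: tuple[float, float]

    @property
    def or_range(self) -> tuple[float, float]:
        return float(self.grid["odds_ratio"].min()), float(self.grid["odds_ratio"].max())

    @property
    def flagged_fraction(self) -> float:
        return float((self.grid["flag"] != "none").mean())

    def flagged_points(self) -> pd.DataFrame:
        return self.grid[self.grid["flag"] != "none"]


def _build_design(
    meta: pd.DataFrame, covariates: list[CovariateSpec]
) -> tuple[np.ndarray | None, list[str], dict[str, list[int]], list[CovariateSpec]]:
    cols, names, cmap, resolved = [], ["(intercept)"], {}, []
    idx = 1  # column 0 is the intercept added by the backend
    for cov in covariates:
        if cov.name not in meta.columns:
            raise ValueError(f"covariate {cov.name!r} not in metadata")
        series = meta[cov.name]
        if cov.kind == "continuous":
            x = series.to_numpy(dtype=float)
            iqr = cov.iqr if cov.iqr is not None else float(np.subtract(*np.percentile(x, [75, 25])))
            if iqr <= 0:
                raise ValueError(f"covariate {cov.name!r} has non-positive IQR")
            cols.append(x)
            names.append(cov.name)
            cmap[cov.name] = [idx]
            idx += 1
            resolved.append(CovariateSpec(cov.name, "continuous", iqr=iqr, note=cov.note))
        else:
            levels = list(pd.unique(series))
            ref = cov.reference if cov.reference is not None else levels[0]
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} not observed for {cov.name!r}")
            others = [l for l in levels if l != ref]
            cids = []
            for lev in others:
                cols.append((series == lev).to_numpy(dtype=float))
                names.append(f"{cov.name}[{lev}]")
                cids.append(idx)
                idx += 1
            cmap[cov.name] = cids
            resolved.append(CovariateSpec(cov.name, "categorical", reference=ref, note=cov.note))
    X = np.column_stack(cols) if cols else None
    return X, names, cmap, resolved


def fit_gam(
    labels: SmmeLabelSet,
    meta: pd.DataFrame,
    covariates: list[CovariateSpec] | None = None,
    backend: str = "spline",
    **backend_kwargs,
) -> GamModel:
    """Fit the high-SMME logistic GAM with a bivariate location smooth.

    ``meta`` must carry projected planar ``x``/``y`` in meters and any
    covariate columns; the binary outcome is high (1) vs low (0) from
    ``labels``, row-aligned with ``meta``.
    """
    meta = meta.reset_index(drop=True)
    y = (labels.labels.reset_index(drop=True) == "high").to_numpy(dtype=float)
    if len(y) != len(meta):
        raise ValueError("labels and metadata are not row-aligned")
    if len(y) < 100:
        raise ValueError("at least 100 labeled predictions required for a stable fit")
    for c in ("x", "y"):
        if c not in meta.columns:
            raise ValueError(f"metadata must contain projected coordinate column {c!r}")
    coords = meta[["x", "y"]].to_numpy(dtype=float)
    covariates = covariates or []
    X_par, names, cmap, resolved = _build_design(meta, covariates)
    if backend == "spline":
        model = SplineLogisticGAM(**backend_kwargs)
    elif backend == "loess":
        model = LoessLogisticGAM(**backend_kwargs)
    else:
        raise ValueError(f"unknown backend {backend!r} (use 'spline' or 'loess')")
    model.fit(coords, X_par, y)
    if not np.isfinite(model.mu_).all() or model.mu_.min() <= 0 or model.mu_.max() >= 1:
        raise RuntimeError(
            "fitted probabilities degenerate (possible separation); "
            f"range [{model.mu_.min():.3g}, {model.mu_.max():.3g}]"
        )
    return GamModel(
        backend=model,
        covariates=resolved,
        column_names=names,
        column_map=cmap,
        coords=coords,
        deviance=model.deviance_,
        edf=model.edf_,
        smooth_p=model.smooth_p_,
    )


def predict_surface(
    model: GamModel,
    n_grid: int = 50,
    spacing: float | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> GamSurface:
    """Odds-ratio surface on an even grid clipped to the convex hull.

    ``spacing`` (meters) overrides ``n_grid`` cells per axis.  A point is
    flagged ``hot`` (``cold``) when its two-sided (1 - alpha) pointwise
    band on the log odds ratio lies entirely above (below) zero.
    """
    if spacing is not None and spacing <= 0:
        raise ValueError("grid spacing must be > 0")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    x, y = model.coords[:, 0], model.coords[:, 1]
    if spacing is None:
        gx = np.linspace(x.min(), x.max(), n_grid)
        gy = np.linspace(y.min(), y.max(), n_grid)
    else:
        gx = np.arange(x.min(), x.max() + spacing, spacing)
        gy = np.arange(y.min(), y.max() + spacing, spacing)
    gxx, gyy = np.meshgrid(gx, gy)
    pts = np.column_stack([gxx.ravel(), gyy.ravel()])
    hull = MultiPoint(model.coords).convex_hull
    shapely.prepare(hull)
    inside = shapely.contains_xy(hull, pts[:, 0], pts[:, 1])
    pts = pts[inside]
    if pts.shape[0] == 0:
        raise ValueError("no grid points fall inside the convex hull of the observations")
    s, se = model.backend.smooth_at(pts[:, 0], pts[:, 1])
    zcrit = stats.norm.ppf(1.0 - alpha / 2.0)
    flag = np.where(s - zcrit * se > 0, "hot", np.where(s + zcrit * se < 0, "cold", "none"))
    grid = pd.DataFrame(
        {
            "x": pts[:, 0],
            "y": pts[:, 1],
            "log_or": s,
            "se": se,
            "odds_ratio": np.exp(s),
            "flag": flag,
        }
    )
    dx = float(gx[1] - gx[0]) if len(gx) > 1 else 0.0
    dy = float(gy[1] - gy[0]) if len(gy) > 1 else 0.0
    return GamSurface(grid=grid, alpha=alpha, spacing=(dx, dy))


def covariate_odds_ratios(model: GamModel, conf_level: float = 0.95) -> pd.DataFrame:
    """Odds ratios with Wald CIs, per IQR for continuous covariates.

    Continuous: OR = exp(beta * IQR).  Categorical: each level vs the
    reference (reported with OR 1 and no CI for the reference itself).
    """
    table = model.backend.parametric_table()
    z = stats.norm.ppf(0.5 + conf_level / 2.0)
    rows = []
    for cov in model.covariates:
        if cov.kind == "continuous":
            (idx,) = model.column_map[cov.name]
            beta, se = table[idx]
            rows.append(
                {
                    "covariate": cov.name,
                    "level": "",
                    "scale": f"per IQR ({cov.iqr:g})",
                    "odds_ratio": float(np.exp(beta * cov.iqr)),
                    "ci_low": float(np.exp((beta - z * se) * cov.iqr)),
                    "ci_high": float(np.exp((beta + z * se) * cov.iqr)),
                    "p_value": float(2 * stats.norm.sf(abs(beta / se))) if se > 0 else np.nan,
                }
            )
        else:
            rows.append(
                {
                    "covariate": cov.name,
                    "level": str(cov.reference),
                    "scale": "reference",
                    "odds_ratio": 1.0,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "p_value": np.nan,
                }
            )
            for idx in model.column_map[cov.name]:
                beta, se = table[idx]
                rows.append(
                    {
                        "covariate": cov.name,
                        "level": model.column_names[idx].split("[", 1)[1].rstrip("]"),
                        "scale": "vs reference",
                        "odds_ratio": float(np.exp(beta)),
                        "ci_low": float(np.exp(beta - z * se)),
                        "ci_high": float(np.exp(beta + z * se)),
                        "p_value": float(2 * stats.norm.sf(abs(beta / se))) if se > 0 else np.nan,
                    }
                )
    return pd.DataFrame(rows)


def _flag_jaccard(a: GamSurface, b: GamSurface) -> float:
    fa = set(map(tuple, np.round(a.flagged_points()[["x", "y"]].to_numpy(), 6)))
    fb = set(map(tuple, np.round(b.flagged_points()[["x", "y"]].to_numpy(), 6)))
    if not fa and not fb:
        return 1.0
    union = fa | fb
    return len(fa & fb) / len(union)


def iterative_covariate_selection(
    labels: SmmeLabelSet,
    meta: pd.DataFrame,
    candidates: list[CovariateSpec],
    backend: str = "spline",
    n_grid: int = 50,
    alpha: float = DEFAULT_ALPHA,
    range_change_threshold: float = 0.10,
    **backend_kwargs,
) -> dict:
    """Add candidates one at a time; retain those moving the OR range >= 10%.

    Returns the selected covariate list, the final joint model and surface,
    and a per-step report (OR ranges, relative changes, flagged-area
    Jaccard overlap with the previous step) for human review of
    pattern changes.
    """
    if not candidates:
        raise ValueError("candidate list must be non-empty")
    selected: list[CovariateSpec] = []
    base_model = fit_gam(labels, meta, selected, backend=backend, **backend_kwargs)
    base_surface = predict_surface(base_model, n_grid=n_grid, alpha=alpha)
    steps = []
    current_surface = base_surface
    for cand in candidates:
        trial = selected + [cand]
        model = fit_gam(labels, meta, trial, backend=backend, **backend_kwargs)
        surface = predict_surface(model, n_grid=n_grid, alpha=alpha)
        lo0, hi0 = current_surface.or_range
        lo1, hi1 = surface.or_range
        span0 = hi0 - lo0
        changes = [
            abs(hi1 - lo1 - span0) / span0 if span0 > 0 else np.inf,
            abs(lo1 - lo0) / abs(lo0) if lo0 != 0 else np.inf,
            abs(hi1 - hi0) / abs(hi0) if hi0 != 0 else np.inf,
        ]
        rel_change = float(np.nanmax(changes))
        retained = rel_change >= range_change_threshold
        steps.append(
            {
                "candidate": cand.name,
                "or_range_before": (lo0, hi0),
                "or_range_after": (lo1, hi1),
                "relative_range_change": rel_change,
                "flag_jaccard_vs_previous": _flag_jaccard(current_surface, surface),
                "flagged_fraction": surface.flagged_fraction,
                "retained": retained,
            }
        )
        if retained:
            selected.append(cand)
            current_surface = surface
    final_model = fit_gam(labels, meta, selected, backend=backend, **backend_kwargs)
    final_surface = predict_surface(final_model, n_grid=n_grid, alpha=alpha)
    return {
        "selected": selected,
        "steps": pd.DataFrame(steps),
        "model": final_model,
        "surface": final_surface,
        "unadjusted_surface": base_surface,
        "unadjusted_model": base_model,
    }


def surface_to_geojson(surface: GamSurface, path: str | Path | None = None) -> dict:
    """GeoJSON FeatureCollection of grid points with or/se/flag properties."""
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [float(r.x), float(r.y)]},
            "properties": {"or": float(r.odds_ratio), "se": float(r.se), "flag": r.flag},
        }
        for r in surface.grid.itertuples()
    ]
    fc = {
        "type": "FeatureCollection",
        "features": features,
        "properties": {"alpha": surface.alpha, "spacing": list(surface.spacing)},
    }
    if path is not None:
        Path(path).write_text(json.dumps(fc))
    return fc
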
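"""Synthetic ensemble-prediction generator for the SUMA error model.

The generative model treats an ensemble of exposure predictions as a
dosimetry system: each replicate k of prediction i is

    X_i^(k) = eps_SM^(k) * eps_Mi^(k) * Z_i + eps_SA^(k) + eps_Ai^(k)

where eps_SM (shared multiplicative) and eps_Mi (unshared multiplicative)
have mean 1 and variances sigma_SM^2, sigma_M^2, and eps_SA / eps_Ai
(shared / unshared additive) have mean 0 and variances sigma_SA^2,
sigma_A^2.  The shared multiplicative factor is hierarchical: one global
draw per replicate (variance sigma_SM^2) shared by every prediction, times
an extra mean-1 draw per *sharing unit* (a group or hotspot region crossed
with time period) whose variance adds the unit's surplus shared error.
For predictions i, j with sharing units u, v this gives

    Cov(X_i, X_j) = S_uv * Z_i * Z_j + sigma_SA^2 [same unit]
    S_uv = (1+sigma_SM^2)(1+x_u) - 1   if u == v  (x_u: unit extra)
         = sigma_SM^2                  if u != v
    Var(X_i)      = Z_i^2 [(1+S_uu)(1+sigma_M^2) - 1]
                    + sigma_SA^2 + sigma_A^2

so with a single global unit these are exactly the moment relations the
SUMA estimators invert, and units with extra shared error covary more
strongly within themselves while still sharing the global error with
everyone else.

Multiplicative errors are lognormal re-parameterised to mean exactly 1 and
the target variance (keeping factors positive); additive errors are normal.
Only the first two moments enter the estimators, so a gamma family is also
offered to demonstrate family-robustness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .io import EnsembleTable

__all__ = [
    "PeriodSpec",
    "HotspotSpec",
    "SimCovariate",
    "SimulationSpec",
    "SimulationTruth",
    "simulate",
    "simulate_study",
    "study_spec",
]


@dataclass
class PeriodSpec:
    """A time stratum with its own error-component multipliers.

    ``weight`` is the sampling probability of the stratum; the four
    multipliers scale the base variance components inside the stratum.
    """

    label: str
    weight: float = 1.0
    sm2_mult: float = 1.0
    m2_mult: float = 1.0
    sa2_mult: float = 1.0
    a2_mult: float = 1.0
    start: str | None = None  # inclusive ISO date, used to draw dates
    end: str | None = None  # inclusive ISO date


@dataclass
class HotspotSpec:
    """A disc of extra *shared* multiplicative error.

    Predictions falling inside the disc form their own sharing unit with
    shared-multiplicative variance ``sigma_SM^2 + extra_sm2``.
    """

    x: float
    y: float
    radius: float
    extra_sm2: float = 0.0
    label: str = "hotspot"


@dataclass
class SimCovariate:
    """A normal covariate whose mean may shift inside named regions."""

    name: str
    mean: float
    sd: float
    region_shift: dict[str, float] = field(default_factory=dict)
    lower: float | None = 0.0  # clip floor (densities/distances are >= 0)


@dataclass
class SimulationSpec:
    """Full configuration of a synthetic ensemble study."""

    n_pred: int = 1000
    n_ens: int = 120
    sigma_sm2: float = 0.0003
    sigma_m2: float = 0.0075
    sigma_sa2: float = 0.0
    sigma_a2: float = 0.0
    z_dist: Literal["uniform", "lognormal"] = "uniform"
    z_params: tuple[float, float] = (10.0, 100.0)
    sharing: Literal["global", "grouped"] = "global"
    group_labels: Sequence[str] | None = None
    group_extra_sm2: dict[str, float] = field(default_factory=dict)
    region_z_scale: dict[str, float] = field(default_factory=dict)
    extent: tuple[float, float, float, float] = (0.0, 0.0, 200_000.0, 150_000.0)
    hotspots: list[HotspotSpec] = field(default_factory=list)
    periods: list[PeriodSpec] = field(default_factory=list)
    covariates: list[SimCovariate] = field(default_factory=list)
    error_family: Literal["lognormal", "gamma"] = "lognormal"
    truncate_negative: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_pred < 1:
            raise ValueError("n_pred must be >= 1")
        if self.n_ens < 2:
            raise ValueError("n_ens >= 2 required (variances across replicates)")
        for name, v in [
            ("sigma_sm2", self.sigma_sm2),
            ("sigma_m2", self.sigma_m2),
            ("sigma_sa2", self.sigma_sa2),
            ("sigma_a2", self.sigma_a2),
        ]:
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.sharing == "grouped":
            if self.group_labels is None or len(self.group_labels) != self.n_pred:
                raise ValueError("grouped sharing requires one group label per prediction")
        x0, y0, x1, y1 = self.extent
        if not (x1 > x0 and y1 > y0):
            raise ValueError("extent must be (x0, y0, x1, y1) with x1 > x0, y1 > y0")
        for h in self.hotspots:
            if not (x0 <= h.x <= x1 and y0 <= h.y <= y1):
                raise ValueError(f"hotspot {h.label!r} centre outside the extent")
            if h.radius <= 0:
                raise ValueError("hotspot radius must be > 0")
            if h.extra_sm2 < 0:
                raise ValueError("hotspot extra_sm2 must be >= 0")
        if self.periods:
            w = np.array([p.weight for p in self.periods], dtype=float)
            if (w < 0).any() or w.sum() <= 0:
                raise ValueError("period weights must be >= 0 and sum > 0")
            for p in self.periods:
                if p.sm2_mult < 1.0:
                    raise ValueError(
                        "period sm2_mult must be >= 1: the global shared factor is common "
                        "to all periods, so a period's shared variance cannot fall below it"
                    )


@dataclass
class SimulationTruth:
    """Everything needed to score parameter recovery against the generator."""

    spec: SimulationSpec
    z: np.ndarray  # generative (error-free) exposure per prediction
    unit: np.ndarray  # sharing-unit label per prediction (group x period)
    region: np.ndarray  # region label per prediction ("hotspot" labels or "other")
    period: np.ndarray  # period label per prediction
    components: pd.DataFrame  # per (unit) effective variance components


def _mult_errors(rng: np.random.Generator, var: float, size, family: str) -> np.ndarray:
    """Positive errors with mean exactly 1 and the requested variance."""
    if var == 0:
        return np.ones(size)
    if family == "lognormal":
        s2 = np.log1p(var)
        return rng.lognormal(mean=-s2 / 2.0, sigma=np.sqrt(s2), size=size)
    if family == "gamma":
        shape = 1.0 / var
        return rng.gamma(shape=shape, scale=var, size=size)
    raise ValueError(f"unknown error family {family!r}")


def _draw_z(rng: np.random.Generator, spec: SimulationSpec) -> np.ndarray:
    a, b = spec.z_params
    if spec.z_dist == "uniform":
        return rng.uniform(a, b, size=spec.n_pred)
    if spec.z_dist == "lognormal":
        return rng.lognormal(mean=a, sigma=b, size=spec.n_pred)
    raise ValueError(f"unknown z distribution {spec.z_dist!r}")


def _assign_dates(rng: np.random.Generator, periods: list[PeriodSpec], labels: np.ndarray) -> np.ndarray:
    """Uniform dates within each period's [start, end] window."""
    out = np.empty(labels.shape[0], dtype="datetime64[D]")
    for p in periods:
        m = labels == p.label
        if not m.any():
            continue
        if p.start is None or p.end is None:
            out[m] = np.datetime64("2000-01-01")
            continue
        lo = np.datetime64(p.start)
        hi = np.datetime64(p.end)
        span = int((hi - lo) / np.timedelta64(1, "D")) + 1
        out[m] = lo + rng.integers(0, span, size=int(m.sum())).astype("timedelta64[D]")
    return out


def simulate(spec: SimulationSpec) -> tuple[EnsembleTable, pd.DataFrame, SimulationTruth]:
    """Draw an ensemble table, its metadata, and the generative truth record.

    Returns
    -------
    table : EnsembleTable
        ``n_pred`` x ``n_ens`` realizations of the SUMA model.
    meta : pandas.DataFrame
        One row per prediction: ``prediction_id``, planar ``x``/``y`` (m),
        ``date``, ``period``, ``region``, plus any configured covariates.
    truth : SimulationTruth
        Generative Z, sharing-unit labels and per-unit effective components.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n, k = spec.n_pred, spec.n_ens

    z = _draw_z(rng, spec)
    x0, y0, x1, y1 = spec.extent
    xs = rng.uniform(x0, x1, size=n)
    ys = rng.uniform(y0, y1, size=n)

    # Region labels: hotspot discs override the background region.
    region = np.full(n, "other", dtype=object)
    extra_sm2 = np.zeros(n)
    for h in spec.hotspots:
        inside = (xs - h.x) ** 2 + (ys - h.y) ** 2 <= h.radius**2
        region[inside] = h.label
        extra_sm2[inside] = h.extra_sm2

    # Sharing group: configured labels (grouped) or hotspot membership.
    if spec.sharing == "grouped":
        group = np.asarray(spec.group_labels, dtype=object)
        extra = np.array([spec.group_extra_sm2.get(g, 0.0) for g in group])
        extra_sm2 = extra_sm2 + extra
    else:
        group = region.copy() if spec.hotspots else np.full(n, "global", dtype=object)

    # Period labels and per-period multipliers.
    if spec.periods:
        w = np.array([p.weight for p in spec.periods], dtype=float)
        w = w / w.sum()
        idx = rng.choice(len(spec.periods), size=n, p=w)
        period = np.array([spec.periods[i].label for i in idx], dtype=object)
        mult = {p.label: p for p in spec.periods}
        dates = _assign_dates(rng, spec.periods, period)
    else:
        period = np.full(n, "all", dtype=object)
        mult = {"all": PeriodSpec("all")}
        dates = np.full(n, np.datetime64("2000-01-01"), dtype="datetime64[D]")

    for reg, scale in spec.region_z_scale.items():
        z[region == reg] *= scale

    # Sharing units are group x period.  The shared multiplicative factor
    # is hierarchical: one global draw per replicate (variance sigma_sm2)
    # common to every unit, times a per-unit extra draw sized so the
    # within-unit total shared variance hits the unit's target.
    unit = np.array([f"{g}|{p}" for g, p in zip(group, period)], dtype=object)
    unit_labels, unit_idx = np.unique(unit, return_inverse=True)

    eps_global = _mult_errors(rng, spec.sigma_sm2, k, spec.error_family)
    base = spec.sigma_sm2

    values = np.empty((n, k))
    comp_rows = []
    for u, ulab in enumerate(unit_labels):
        members = unit_idx == u
        p = mult[str(ulab).split("|")[1]]
        target_sm2 = base * p.sm2_mult + float(extra_sm2[members][0])
        # extra variance so that (1+base)(1+x) - 1 == target_sm2
        x_u = (1.0 + target_sm2) / (1.0 + base) - 1.0
        m2 = spec.sigma_m2 * p.m2_mult
        sa2 = spec.sigma_sa2 * p.sa2_mult
        a2 = spec.sigma_a2 * p.a2_mult
        nm = int(members.sum())
        eps_extra = _mult_errors(rng, x_u, k, spec.error_family)  # one per replicate
        eps_sm = eps_global * eps_extra
        eps_sa = rng.normal(0.0, np.sqrt(sa2), size=k) if sa2 > 0 else np.zeros(k)
        eps_m = _mult_errors(rng, m2, (nm, k), spec.error_family)
        eps_a = rng.normal(0.0, np.sqrt(a2), size=(nm, k)) if a2 > 0 else 0.0
        values[members] = eps_sm[None, :] * eps_m * z[members, None] + eps_sa[None, :] + eps_a
        comp_rows.append(
            {"unit": ulab, "n_pred": nm, "sigma_sm2": target_sm2, "extra_sm2": x_u,
             "sigma_m2": m2, "sigma_sa2": sa2, "sigma_a2": a2}
        )

    if spec.truncate_negative:
        np.clip(values, 0.0, None, out=values)

    ids = np.array([f"p{i:06d}" for i in range(n)], dtype=object)
    meta = pd.DataFrame(
        {
            "prediction_id": ids,
            "x": xs,
            "y": ys,
            "date": pd.to_datetime(dates),
            "period": period,
            "region": region,
        }
    )
    for cov in spec.covariates:
        vals = rng.normal(cov.mean, cov.sd, size=n)
        for reg, shift in cov.region_shift.items():
            vals[region == reg] += shift
        if cov.lower is not None:
            np.clip(vals, cov.lower, None, out=vals)
        meta[cov.name] = vals

    table = EnsembleTable(prediction_ids=ids, values=values)
    truth = SimulationTruth(
        spec=spec,
        z=z,
        unit=unit,
        region=region,
        period=period,
        components=pd.DataFrame(comp_rows),
    )
    return table, meta, truth


def study_spec(
    n_pred: int = 6000,
    n_ens: int = 120,
    seed: int = 0,
    region_extra_sm2: float = 0.002,
    region_radius: float = 24_000.0,
) -> SimulationSpec:
    """Configuration of the default synthetic study.

    Emulates a Southern-California-shaped prediction set: NOx exposures
    lognormal around ~30 ppb, three calendar-year tertiles whose shared
    multiplicative variance decreases over time (0.00036 / 0.00015 /
    0.00014), and one densely populated harbour region ("synthetic Long
    Beach", a disc covering roughly 6% of the extent) carrying strong extra
    shared multiplicative error (within-region shared variance ~0.0021),
    elevated exposures (the mean-covariance screen partly reflects absolute
    exposure levels), and elevated urban covariates (traffic density,
    population density, dispersion-model non-freeway NOx).  Unshared
    multiplicative variance is 0.0075; additive components are zero.
    """
    base_sm2 = 0.00014
    x0, y0, x1, y1 = 0.0, 0.0, 200_000.0, 150_000.0
    return SimulationSpec(
        n_pred=n_pred,
        n_ens=n_ens,
        sigma_sm2=base_sm2,
        sigma_m2=0.0075,
        sigma_sa2=0.0,
        sigma_a2=0.0,
        z_dist="lognormal",
        z_params=(np.log(30.0), 0.6),
        extent=(x0, y0, x1, y1),
        hotspots=[
            HotspotSpec(x=60_000.0, y=30_000.0, radius=region_radius, extra_sm2=region_extra_sm2, label="long_beach")
        ],
        region_z_scale={"long_beach": 1.8},
        periods=[
            PeriodSpec("1992-2000", weight=0.33, sm2_mult=0.00036 / base_sm2, start="1992-01-01", end="2000-12-31"),
            PeriodSpec("2001-2004", weight=0.30, sm2_mult=0.00015 / base_sm2, start="2001-01-01", end="2004-12-31"),
            PeriodSpec("2005-2012", weight=0.37, sm2_mult=1.0, start="2005-01-01", end="2012-12-31"),
        ],
        covariates=[
            SimCovariate("traffic_density", mean=45.0, sd=25.0, region_shift={"long_beach": 75.0}),
            SimCovariate("population_density", mean=5000.0, sd=2500.0, region_shift={"long_beach": 11000.0}),
            SimCovariate("nonfreeway_nox", mean=5.0, sd=3.0, region_shift={"long_beach": 15.0}),
            SimCovariate("min_temperature", mean=12.0, sd=4.0, lower=None),
        ],
        seed=seed,
    )


def simulate_study(spec: SimulationSpec | None = None, seed: int | None = None, **kwargs):
    """Generate the full synthetic study fixture (ensembles + rich metadata).

    ``spec`` defaults to :func:`study_spec`; ``seed``/keyword overrides are
    forwarded to it.  Returns the same triple as :func:`simulate`.
    """
    if spec is None:
        if seed is not None:
            kwargs["seed"] = seed
        spec = study_spec(**kwargs)
    elif seed is not None:
        spec.seed = seed
    return simulate(spec)
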
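"""SUMA variance-component estimation from ensemble realizations.

The measurement-error model for a prediction i with estimated exposure Z_i
and true exposure X_i is

    X_i = eps_SM * eps_Mi * Z_i + eps_SA + eps_Ai

with multiplicative errors of mean 1 (variances sigma_SM^2 shared,
sigma_M^2 unshared) and additive errors of mean 0 (variances sigma_SA^2
shared, sigma_A^2 unshared).  Treating the ensemble replicates as
realizations of X_i, the model implies two moment relations:

    Cov(X_i, X_j) = sigma_SA^2 + sigma_SM^2 * Z_i Z_j        (i != j)
    Var(X_i)      = sigma_SA^2 + sigma_A^2
                    + [(1+sigma_SM^2)(1+sigma_M^2) - 1] * Z_i^2

Estimation is therefore two ordinary least squares fits: the pairwise
across-replicate covariance C_ij on the product of means Z_i Z_j (the
"shared" regression: intercept -> sigma_SA^2, slope -> sigma_SM^2), and the
per-prediction across-replicate variance V_i on Z_i^2 (the "unshared"
regression: intercept -> sigma_SA^2 + sigma_A^2, slope -> the bracketed
total relative variance).  Negative raw estimates are truncated at zero
before the multiplicative components are solved.

Reported OLS standard errors and p-values are nominal: pair records share
indices and replicates, so they are descriptive, not exact inferential
quantities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import EnsembleTable, SampleSpec, subsample

__all__ = [
    "RegressionFit",
    "SumaComponents",
    "SumaResult",
    "summarize_predictions",
    "pairwise_stats",
    "fit_shared_regression",
    "fit_unshared_regression",
    "solve_components",
    "run_suma",
    "stratified_suma",
]


@dataclass
class RegressionFit:
    """Intercept/slope of a simple OLS fit with nominal SEs and p-values."""

    intercept: float
    slope: float
    intercept_se: float
    slope_se: float
    intercept_p: float
    slope_p: float
    n_obs: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class SumaComponents:
    """The four error variances, truncated at zero, with raw estimates.

    ``sigma_sm2``/``sigma_sa2`` come from the shared (pairwise covariance)
    regression, ``sigma_m2``/``sigma_a2`` from the unshared (variance)
    regression after removing the shared contributions.  ``truncated``
    records which components had a negative raw estimate set to zero.
    """

    sigma_sm2: float
    sigma_m2: float
    sigma_sa2: float
    sigma_a2: float
    shared_fit: RegressionFit
    unshared_fit: RegressionFit
    truncated: dict[str, bool] = field(default_factory=dict)

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "sigma_sm2": self.sigma_sm2,
                "sigma_m2": self.sigma_m2,
                "sigma_sa2": self.sigma_sa2,
                "sigma_a2": self.sigma_a2,
            }
        )

    def to_dict(self) -> dict:
        return {
            "components": self.as_series().to_dict(),
            "truncated": dict(self.truncated),
            "shared_fit": self.shared_fit.to_dict(),
            "unshared_fit": self.unshared_fit.to_dict(),
        }


@dataclass
class SumaResult:
    """End-to-end decomposition output, with per-repeat detail."""

    components: SumaComponents  # first repeat (the headline sample)
    per_repeat: list[SumaComponents]
    summary: pd.DataFrame  # per-repeat component values

    def spread(self) -> pd.DataFrame:
        """Across-repeat mean, SD and range of each component."""
        return self.summary.agg(["mean", "std", "min", "max"])


def _row_means(table: EnsembleTable, weights: np.ndarray | None) -> np.ndarray:
    if weights is None:
        return table.values.mean(axis=1)
    w = np.asarray(weights, dtype=float)
    if w.shape != (table.n_ens,) or (w < 0).any() or w.sum() <= 0:
        raise ValueError("weights must be one non-negative value per replicate, not all zero")
    return table.values @ (w / w.sum())


def summarize_predictions(table: EnsembleTable, weights: np.ndarray | None = None) -> pd.DataFrame:
    """Per-prediction across-replicate mean ``z``, variance ``v`` and ``z2``.

    Sample (n_ens - 1) denominators throughout: the replicates are a sample
    from the dosimetry distribution, not the full population.  ``weights``
    (one per replicate, e.g. ensemble performance weights) make ``z`` a
    weighted mean; the default estimate is unweighted.  The variance stays
    unweighted — it is the dosimetry spread, not an estimate of Z.
    """
    z = _row_means(table, weights)
    v = table.values.var(axis=1, ddof=1)
    return pd.DataFrame(
        {"prediction_id": table.prediction_ids, "z": z, "v": v, "z2": z * z}
    )


def pairwise_stats(
    table: EnsembleTable, block_size: int = 512, weights: np.ndarray | None = None
) -> pd.DataFrame:
    """All unordered pairs' across-replicate covariance and mean product.

    Returns a frame with integer row indices ``i < j``, ``c`` (sample
    covariance of the two rows across replicates, ddof=1) and ``zz``
    (product of the two row means — weighted means when ``weights`` are
    given).  Computed blockwise so the ~3.1 M pairs of a 2500-prediction
    table stream through ordinary memory.
    """
    n, k = table.n_pred, table.n_ens
    if n < 2:
        raise ValueError("pairwise statistics require at least 2 predictions")
    z = _row_means(table, weights)
    dev = table.values - table.values.mean(axis=1, keepdims=True)
    ii, jj, cc, zzs = [], [], [], []
    for a0 in range(0, n, block_size):
        a1 = min(a0 + block_size, n)
        # covariance of rows [a0:a1] with rows [a0:n] in one matmul
        cov = dev[a0:a1] @ dev[a0:].T / (k - 1)
        prod = np.outer(z[a0:a1], z[a0:])
        r, c = np.triu_indices(a1 - a0, k=1, m=n - a0)
        ii.append(r + a0)
        jj.append(c + a0)
        cc.append(cov[r, c])
        zzs.append(prod[r, c])
    return pd.DataFrame(
        {
            "i": np.concatenate(ii),
            "j": np.concatenate(jj),
            "c": np.concatenate(cc),
            "zz": np.concatenate(zzs),
        }
    )


def _simple_ols(y: np.ndarray, x: np.ndarray) -> RegressionFit:
    if y.size < 3:
        raise ValueError("at least 3 observations required for the OLS fit")
    if np.ptp(x) == 0:
        raise ValueError("degenerate regressor: all values identical")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionFit(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        intercept_se=float(res.bse[0]),
        slope_se=float(res.bse[1]),
        intercept_p=float(res.pvalues[0]),
        slope_p=float(res.pvalues[1]),
        n_obs=int(res.nobs),
    )


def fit_shared_regression(pairs: pd.DataFrame) -> RegressionFit:
    """OLS of pairwise covariance on the product of means.

    The intercept estimates the shared additive variance sigma_SA^2; the
    slope estimates the shared multiplicative variance sigma_SM^2.
    Self-pairs are never included: within-prediction variance is the
    unshared regression's business.
    """
    return _simple_ols(pairs["c"].to_numpy(), pairs["zz"].to_numpy())


def fit_unshared_regression(summaries: pd.DataFrame) -> RegressionFit:
    """OLS of across-replicate variance on the squared mean.

    The intercept estimates sigma_SA^2 + sigma_A^2; the slope estimates the
    total relative variance (1+sigma_SM^2)(1+sigma_M^2) - 1.
    """
    return _simple_ols(summaries["v"].to_numpy(), summaries["z2"].to_numpy())


def solve_components(shared_fit: RegressionFit, unshared_fit: RegressionFit) -> SumaComponents:
    """Solve the two regressions for the four variance components.

    Truncation order matters and follows the moment relations: sigma_SM^2
    is truncated at zero *before* dividing it out of the total relative
    variance for sigma_M^2, and sigma_SA^2 is truncated before it is
    differenced out of the unshared intercept for sigma_A^2.
    """
    if unshared_fit.slope <= -1.0:
        raise ValueError(
            f"unshared regression slope {unshared_fit.slope:g} <= -1: total relative variance would be negative"
        )
    truncated = {
        "sigma_sm2": shared_fit.slope < 0,
        "sigma_sa2": shared_fit.intercept < 0,
    }
    sigma_sm2 = max(shared_fit.slope, 0.0)
    sigma_sa2 = max(shared_fit.intercept, 0.0)
    raw_m2 = (1.0 + unshared_fit.slope) / (1.0 + sigma_sm2) - 1.0
    truncated["sigma_m2"] = raw_m2 < 0
    sigma_m2 = max(raw_m2, 0.0)
    raw_a2 = unshared_fit.intercept - sigma_sa2
    truncated["sigma_a2"] = raw_a2 < 0
    sigma_a2 = max(raw_a2, 0.0)
    return SumaComponents(
        sigma_sm2=sigma_sm2,
        sigma_m2=sigma_m2,
        sigma_sa2=sigma_sa2,
        sigma_a2=sigma_a2,
        shared_fit=shared_fit,
        unshared_fit=unshared_fit,
        truncated=truncated,
    )


def decompose_table(table: EnsembleTable) -> SumaComponents:
    """Full decomposition of one ensemble table (no subsampling)."""
    summaries = summarize_predictions(table)
    pairs = pairwise_stats(table)
    return solve_components(fit_shared_regression(pairs), fit_unshared_regression(summaries))


def run_suma(table: EnsembleTable, meta: pd.DataFrame, spec: SampleSpec) -> SumaResult:
    """Subsample then decompose; repeats assess sampling robustness.

    The first repeat is the headline sample; the remaining repeats re-run
    the identical analysis on fresh seeded samples so the across-repeat
    spread of the components measures sensitivity to the random draw.
    """
    samples = subsample(table, meta, spec)
    per_repeat = [decompose_table(sub) for sub, _ in samples]
    summary = pd.DataFrame([c.as_series() for c in per_repeat])
    summary.index.name = "repeat"
    return SumaResult(components=per_repeat[0], per_repeat=per_repeat, summary=summary)


def pair_summary(pairs: pd.DataFrame) -> dict:
    """Min/max/median of covariances and mean products (descriptives)."""
    return {
        "min_covariance": float(pairs["c"].min()),
        "max_covariance": float(pairs["c"].max()),
        "median_covariance": float(pairs["c"].median()),
        "min_product_mean": float(pairs["zz"].min()),
        "max_product_mean": float(pairs["zz"].max()),
        "median_product_mean": float(pairs["zz"].median()),
    }


def stratified_suma(
    table: EnsembleTable,
    meta: pd.DataFrame,
    strata_column: str,
    spec: SampleSpec,
) -> dict[str, dict]:
    """Independent subsample + SUMA fit per stratum (e.g. time tertiles).

    Each stratum draws its own random sample of ``spec.sample_size``
    predictions (the whole stratum, with a warning, when it is smaller) and
    runs the full decomposition; pairwise covariance / product-mean
    descriptives accompany each stratum's components.
    """
    if strata_column not in meta.columns:
        raise ValueError(f"unknown strata column {strata_column!r}")
    out: dict[str, dict] = {}
    for level in pd.unique(meta[strata_column]):
        s = SampleSpec(
            sample_size=spec.sample_size,
            n_repeats=1,
            seed=spec.seed,
            stratum=(strata_column, level),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # undersized strata fall back to the whole stratum
            sub, _ = subsample(table, meta, s)[0]
        summaries = summarize_predictions(sub)
        pairs = pairwise_stats(sub)
        comp = solve_components(fit_shared_regression(pairs), fit_unshared_regression(summaries))
        out[str(level)] = {"components": comp, "pair_summary": pair_summary(pairs), "n": sub.n_pred}
    return out
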
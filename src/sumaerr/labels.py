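"""Labeling predictions as carrying high or low shared multiplicative error.

A prediction whose realizations consistently covary with other predictions'
realizations across the ensemble carries elevated shared error.  The "mean
covariance" of prediction i is the average across-replicate covariance
C_ij over all other sampled predictions j; dichotomizing the mean
covariances at a percentile (default the 80th: upper 20% labeled ``high``)
yields the high/low SMME label each downstream comparison and the spatial
model consume.  Ties at the threshold label high (the cut is
"covariance >= threshold").

Because covariances are unstandardized, predictions with large absolute
exposures tend toward larger mean covariances; the label is a screen for
unusually and consistently covarying predictions, not a scale-free
statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SmmeLabelSet",
    "mean_covariances",
    "dichotomize",
    "compare_groups",
    "tabulate_labels",
    "season_of",
]


@dataclass
class SmmeLabelSet:
    """Per-prediction mean covariance and its high/low dichotomization."""

    frame: pd.DataFrame  # prediction_id (optional), mean_cov, label
    threshold: float
    percentile: float

    @property
    def labels(self) -> pd.Series:
        return self.frame["label"]

    @property
    def n_high(self) -> int:
        return int((self.frame["label"] == "high").sum())


def mean_covariances(pairs: pd.DataFrame, n_pred: int | None = None) -> np.ndarray:
    """Average pairwise covariance of each prediction with all others.

    ``pairs`` is the frame from :func:`sumaerr.core.pairwise_stats` (integer
    indices ``i < j``, covariance ``c``).  Every prediction must appear in
    at least one pair.
    """
    i = pairs["i"].to_numpy()
    j = pairs["j"].to_numpy()
    c = pairs["c"].to_numpy()
    n = int(max(i.max(), j.max())) + 1 if n_pred is None else n_pred
    sums = np.bincount(i, weights=c, minlength=n) + np.bincount(j, weights=c, minlength=n)
    counts = np.bincount(i, minlength=n) + np.bincount(j, minlength=n)
    if (counts == 0).any():
        raise ValueError(f"prediction {int(np.argmin(counts))} appears in no pair")
    return sums / counts


def dichotomize(
    mean_covs: np.ndarray,
    percentile: float = 80.0,
    prediction_ids: np.ndarray | None = None,
) -> SmmeLabelSet:
    """Split mean covariances into high (>= percentile cut) and low.

    The threshold is the empirical percentile with the linear-interpolation
    convention (numpy's default), chosen for bit-reproducibility; ties at
    the threshold are labeled high.
    """
    mean_covs = np.asarray(mean_covs, dtype=float)
    if mean_covs.size < 5:
        raise ValueError("at least 5 predictions required to dichotomize")
    if not np.isfinite(mean_covs).all():
        raise ValueError("non-finite mean covariance")
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    threshold = float(np.percentile(mean_covs, percentile))
    label = np.where(mean_covs >= threshold, "high", "low")
    if np.ptp(mean_covs) == 0:
        warnings.warn(
            "all mean covariances identical; every prediction labeled high by the ties rule",
            stacklevel=2,
        )
    frame = pd.DataFrame({"mean_cov": mean_covs, "label": label})
    if prediction_ids is not None:
        frame.insert(0, "prediction_id", np.asarray(prediction_ids, dtype=object))
    return SmmeLabelSet(frame=frame, threshold=threshold, percentile=percentile)


def compare_groups(
    labels: SmmeLabelSet, meta: pd.DataFrame, variables: list[str]
) -> pd.DataFrame:
    """Welch two-sided t-test of each variable across the low/high groups.

    Reports per-variable group means and SDs, the Welch statistic and
    p-value, and the 95% CI of the mean difference (low - high).  A
    variable with zero variance in both groups has an undefined test and is
    reported with NaN statistics.
    """
    lab = labels.labels.to_numpy()
    lo_mask, hi_mask = lab == "low", lab == "high"
    if lo_mask.sum() < 2 or hi_mask.sum() < 2:
        raise ValueError("both label groups need at least 2 members")
    rows = []
    for var in variables:
        if var not in meta.columns:
            raise ValueError(f"unknown variable {var!r}")
        x = meta[var].to_numpy(dtype=float)
        lo, hi = x[lo_mask], x[hi_mask]
        row = {
            "variable": var,
            "low_mean": lo.mean(),
            "low_sd": lo.std(ddof=1),
            "high_mean": hi.mean(),
            "high_sd": hi.std(ddof=1),
            "n_low": lo.size,
            "n_high": hi.size,
        }
        if lo.std(ddof=1) == 0 and hi.std(ddof=1) == 0:
            row.update(statistic=np.nan, p_value=np.nan, ci_low=np.nan, ci_high=np.nan, note="zero variance in both groups")
        else:
            t, p = stats.ttest_ind(lo, hi, equal_var=False)
            se2 = lo.var(ddof=1) / lo.size + hi.var(ddof=1) / hi.size
            df = se2**2 / (
                (lo.var(ddof=1) / lo.size) ** 2 / (lo.size - 1)
                + (hi.var(ddof=1) / hi.size) ** 2 / (hi.size - 1)
            )
            half = stats.t.ppf(0.975, df) * np.sqrt(se2)
            d = lo.mean() - hi.mean()
            row.update(statistic=float(t), p_value=float(p), ci_low=d - half, ci_high=d + half, note="")
        rows.append(row)
    return pd.DataFrame(rows)


_SEASONS = {12: "winter", 1: "winter", 2: "winter",
            3: "spring", 4: "spring", 5: "spring",
            6: "summer", 7: "summer", 8: "summer",
            9: "fall", 10: "fall", 11: "fall"}


def season_of(dates: pd.Series) -> pd.Series:
    """Meteorological season from the calendar month (winter = Dec-Feb)."""
    months = pd.to_datetime(dates).dt.month
    return months.map(_SEASONS)


def tabulate_labels(labels: SmmeLabelSet, meta: pd.DataFrame, by: str) -> pd.DataFrame:
    """Counts and column percentages of low/high labels per category.

    ``by`` may be any metadata column; ``"season"`` is derived from the
    ``date`` column when absent.  Each non-reference category also gets a
    two-sided Welch test of its high-label proportion against the first
    (reference) category.
    """
    meta = meta.reset_index(drop=True)
    if by == "season" and "season" not in meta.columns:
        if "date" not in meta.columns:
            raise ValueError("season tabulation needs a 'date' or 'season' column")
        groups = season_of(meta["date"])
    elif by in meta.columns:
        groups = meta[by]
    else:
        raise ValueError(f"unknown grouping variable {by!r}")
    lab = labels.labels.reset_index(drop=True)
    high = (lab == "high").astype(float)

    cats = list(pd.unique(groups))
    ref = high[groups == cats[0]]
    rows = []
    for k, cat in enumerate(cats):
        mask = (groups == cat).to_numpy()
        n_lo = int(((lab == "low") & mask).sum())
        n_hi = int(((lab == "high") & mask).sum())
        if k == 0 or mask.sum() < 2 or len(ref) < 2:
            p = np.nan
        else:
            _, p = stats.ttest_ind(high[mask], ref, equal_var=False)
        rows.append({by: cat, "n_low": n_lo, "n_high": n_hi, "p_vs_reference": float(p) if p == p else np.nan})
    out = pd.DataFrame(rows)
    tot_lo, tot_hi = out["n_low"].sum(), out["n_high"].sum()
    out["low_pct"] = 100.0 * out["n_low"] / max(tot_lo, 1)
    out["high_pct"] = 100.0 * out["n_high"] / max(tot_hi, 1)
    return out[[by, "n_low", "low_pct", "n_high", "high_pct", "p_vs_reference"]]
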
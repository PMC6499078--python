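"""Data model and file I/O for ensemble prediction sets.

An ensemble prediction set is an ``n_pred x n_ens`` matrix of exposure
realizations (ppb): one row per prediction (a subject-location-biweek
estimate), one column per ensemble replicate.  On disk both the ensemble
matrix and the prediction metadata are plain UTF-8 CSV with a header row;
the first column is always ``prediction_id`` and rows are joined on it —
row order never carries meaning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EnsembleTable",
    "SampleSpec",
    "read_ensemble_table",
    "write_ensemble_table",
    "read_meta",
    "write_meta",
    "validate_meta",
    "subsample",
    "representativeness_report",
]

ID_COL = "prediction_id"


@dataclass
class EnsembleTable:
    """Realizations of predictions across ensemble replicates.

    Parameters
    ----------
    prediction_ids : array of str
        Unique opaque identifiers, one per row.
    values : ndarray, shape (n_pred, n_ens)
        Exposure realizations in ppb; all finite; ``n_ens >= 2``.
    """

    prediction_ids: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.prediction_ids = np.asarray(self.prediction_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix (predictions x replicates)")
        if self.values.shape[1] < 2:
            raise ValueError("n_ens >= 2 required")
        if self.values.shape[0] != self.prediction_ids.shape[0]:
            raise ValueError("prediction_ids length must equal the number of rows")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(f"non-finite value at row {bad[0]}, replicate column {bad[1]}")
        if len(set(self.prediction_ids)) != len(self.prediction_ids):
            raise ValueError("prediction_ids must be unique")

    @property
    def n_pred(self) -> int:
        return self.values.shape[0]

    @property
    def n_ens(self) -> int:
        return self.values.shape[1]

    def select_ids(self, ids: np.ndarray) -> "EnsembleTable":
        """Rows for ``ids``, in the given order; unknown ids are an error."""
        pos = {pid: i for i, pid in enumerate(self.prediction_ids)}
        try:
            rows = np.array([pos[i] for i in ids])
        except KeyError as e:  # pragma: no cover - defensive
            raise KeyError(f"unknown prediction_id {e.args[0]!r}") from None
        return EnsembleTable(self.prediction_ids[rows], self.values[rows])

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"ens_{k + 1:03d}" for k in range(self.n_ens)]
        df = pd.DataFrame(self.values, columns=cols)
        df.insert(0, ID_COL, self.prediction_ids)
        return df


@dataclass
class SampleSpec:
    """Seeded repeated subsampling plan (without replacement per repeat).

    One top-level ``seed`` drives all repeats; repeat ``r`` uses the spawned
    stream ``SeedSequence(seed).spawn()[r]`` so repeats are mutually
    independent but each bit-reproducible.  Draws are independent across
    repeats (membership may overlap between repeats).
    """

    sample_size: int = 2500
    n_repeats: int = 11
    seed: int = 0
    stratum: tuple[str, object] | None = None  # (meta column, value) filter

    def __post_init__(self) -> None:
        if self.sample_size < 1:
            raise ValueError("sample_size must be >= 1")
        if self.n_repeats < 1:
            raise ValueError("n_repeats >= 1 required")


def read_ensemble_table(path: str | Path) -> EnsembleTable:
    """Read an ensemble matrix CSV (``prediction_id,ens_001,...``)."""
    path = Path(path)
    df = pd.read_csv(path, dtype={ID_COL: str}, float_precision="round_trip")
    df[df.columns[0]] = df[df.columns[0]].astype(str)
    if df.shape[1] < 3:
        raise ValueError("n_ens >= 2 required (found fewer than two replicate columns)")
    ids = df.iloc[:, 0].to_numpy(dtype=object)
    if pd.Series(ids).duplicated().any():
        dup = pd.Series(ids)[pd.Series(ids).duplicated()].iloc[0]
        raise ValueError(f"duplicate prediction_id {dup!r} in {path.name}")
    vals = df.iloc[:, 1:]
    numeric = vals.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"missing or non-numeric cell in {path.name}: row id {ids[r]!r}, column {vals.columns[c]!r}"
        )
    return EnsembleTable(prediction_ids=ids, values=numeric.to_numpy(dtype=float))


def write_ensemble_table(table: EnsembleTable, path: str | Path) -> None:
    """Write the matrix as CSV, values at full decimal precision."""
    table.to_dataframe().to_csv(path, index=False, float_format="%.17g")


def validate_meta(meta: pd.DataFrame, require_coords: bool = False) -> pd.DataFrame:
    """Check a metadata table's invariants; returns the (unmodified) frame."""
    if ID_COL not in meta.columns:
        raise ValueError(f"metadata must contain a {ID_COL!r} column")
    if meta[ID_COL].duplicated().any():
        raise ValueError("metadata prediction_id values must be unique")
    if require_coords:
        for c in ("x", "y"):
            if c not in meta.columns:
                raise ValueError(f"metadata must contain projected coordinate column {c!r}")
            if not np.isfinite(meta[c].to_numpy(dtype=float)).all():
                raise ValueError(f"non-finite coordinate in column {c!r}")
    for c in meta.columns:
        if c.startswith("dist") and (pd.to_numeric(meta[c], errors="coerce") < 0).any():
            raise ValueError(f"negative distance in column {c!r}")
    return meta


def read_meta(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, dtype={ID_COL: str}, float_precision="round_trip")
    if "date" in meta.columns:
        meta["date"] = pd.to_datetime(meta["date"])
    return validate_meta(meta)


def write_meta(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, index=False, float_format="%.17g")


def _align_meta(table: EnsembleTable, meta: pd.DataFrame) -> pd.DataFrame:
    """Metadata rows joined to (and ordered as) the table's ids."""
    validate_meta(meta)
    indexed = meta.set_index(ID_COL)
    missing = [i for i in table.prediction_ids if i not in indexed.index]
    if missing:
        raise ValueError(f"{len(missing)} table prediction_ids missing from metadata, e.g. {missing[0]!r}")
    out = indexed.loc[list(table.prediction_ids)].reset_index()
    return out


def subsample(
    table: EnsembleTable, meta: pd.DataFrame, spec: SampleSpec
) -> list[tuple[EnsembleTable, pd.DataFrame]]:
    """Draw ``spec.n_repeats`` seeded samples without replacement.

    Each repeat is an independent draw of ``spec.sample_size`` predictions
    from the (optionally stratum-filtered) population; the same spec always
    reproduces the same samples.  If the stratum holds fewer predictions
    than ``sample_size`` the whole stratum is returned with a warning.
    """
    meta = _align_meta(table, meta)
    pool = np.arange(table.n_pred)
    if spec.stratum is not None:
        col, value = spec.stratum
        if col not in meta.columns:
            raise ValueError(f"unknown stratum column {col!r}")
        pool = pool[(meta[col] == value).to_numpy()]
    size = spec.sample_size
    if size > pool.size:
        warnings.warn(
            f"sample_size {size} exceeds available predictions ({pool.size}); sampling the whole stratum",
            stacklevel=2,
        )
        size = pool.size
    if pool.size == 0:
        raise ValueError("empty sampling population")

    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_repeats)
    out = []
    for ss in streams:
        rng = np.random.default_rng(ss)
        rows = np.sort(rng.choice(pool, size=size, replace=False))
        sub = EnsembleTable(table.prediction_ids[rows], table.values[rows])
        out.append((sub, meta.iloc[rows].reset_index(drop=True)))
    return out


def representativeness_report(
    sample_meta: pd.DataFrame,
    population_meta: pd.DataFrame,
    variables: list[str],
    bins: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Compare sample vs population distributions variable by variable.

    Continuous variables are binned (default: population quartile edges);
    categorical variables use their observed categories.  Returns a tidy
    frame with counts and percentages in both sets and, per variable, the
    maximum absolute percentage-point difference (``max_abs_pct_diff``).
    """
    bins = bins or {}
    rows = []
    for var in variables:
        for frame, name in [(sample_meta, "sample"), (population_meta, "population")]:
            if var not in frame.columns:
                raise ValueError(f"unknown variable {var!r} in {name} metadata")
        pop = population_meta[var]
        smp = sample_meta[var]
        if pd.api.types.is_numeric_dtype(pop):
            edges = np.asarray(bins.get(var, np.nanquantile(pop.to_numpy(dtype=float), [0, 0.25, 0.5, 0.75, 1.0])))
            edges = np.unique(edges)
            labels = [f"{lo:g}-{hi:g}" for lo, hi in zip(edges[:-1], edges[1:])]
            pop_bin = pd.cut(pop, edges, labels=labels, include_lowest=True)
            smp_bin = pd.cut(smp, edges, labels=labels, include_lowest=True)
        else:
            cats = sorted(pop.dropna().unique())
            pop_bin = pd.Categorical(pop, categories=cats)
            smp_bin = pd.Categorical(smp, categories=cats)
            labels = cats
        pop_counts = pd.Series(pop_bin).value_counts(sort=False)
        smp_counts = pd.Series(smp_bin).value_counts(sort=False)
        pop_pct = 100.0 * pop_counts / max(pop_counts.sum(), 1)
        smp_pct = 100.0 * smp_counts / max(smp_counts.sum(), 1)
        diff = (smp_pct - pop_pct).abs()
        for lab in pop_counts.index:
            rows.append(
                {
                    "variable": var,
                    "bin": str(lab),
                    "population_n": int(pop_counts[lab]),
                    "population_pct": float(pop_pct[lab]),
                    "sample_n": int(smp_counts[lab]),
                    "sample_pct": float(smp_pct[lab]),
                    "abs_pct_diff": float(diff[lab]),
                    "max_abs_pct_diff": float(diff.max()),
                }
            )
    return pd.DataFrame(rows)
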
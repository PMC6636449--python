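"""Tabular ingestion, mean imputation, and z-score standardization.

The modelling code works exclusively on standardized (zero-mean, unit-sd)
matrices: features become ``E0`` and responses become ``F0``.  The column
means and standard deviations are retained so that predictions can be mapped
back onto the original response scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DataTable",
    "StandardizedData",
    "read_raw_table",
    "impute_mean",
    "load_table",
    "zscore",
    "destandardize_predictions",
]


@dataclass(frozen=True)
class DataTable:
    """A clean numeric regression table: q samples, p features, L responses.

    All entries must be finite — imputation happens before construction.
    """

    X: np.ndarray
    Y: np.ndarray
    feature_names: tuple[str, ...]
    response_names: tuple[str, ...]

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        Y = np.asarray(self.Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Y", Y)
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        object.__setattr__(self, "response_names", tuple(self.response_names))
        q, p = X.shape
        if q < 2:
            raise ValueError(f"need at least 2 samples, got {q}")
        if p < 1:
            raise ValueError("need at least one feature column")
        if Y.shape[0] != q:
            raise ValueError("X and Y row counts differ")
        if Y.shape[1] < 1:
            raise ValueError("need at least one response column")
        if len(self.feature_names) != p or len(self.response_names) != Y.shape[1]:
            raise ValueError("name lists do not match matrix shapes")
        if not np.isfinite(X).all() or not np.isfinite(Y).all():
            raise ValueError("non-finite entries; impute/clean before building a DataTable")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.feature_names))
        for j, name in enumerate(self.response_names):
            df[name] = self.Y[:, j]
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, response: str | Sequence[str]) -> "DataTable":
        responses = [response] if isinstance(response, str) else list(response)
        missing = [c for c in responses if c not in df.columns]
        if missing:
            raise KeyError(f"response column(s) not found: {missing}")
        features = [c for c in df.columns if c not in responses]
        if not features:
            raise ValueError("no feature columns left after removing responses")
        return cls(
            X=df[features].to_numpy(dtype=float),
            Y=df[responses].to_numpy(dtype=float),
            feature_names=tuple(features),
            response_names=tuple(responses),
        )

    def subset_rows(self, rows: np.ndarray) -> "DataTable":
        return DataTable(self.X[rows], self.Y[rows], self.feature_names, self.response_names)


@dataclass(frozen=True)
class StandardizedData:
    """Centered/scaled matrices E0 (features) and F0 (responses).

    Stores per-column means and sample standard deviations (divisor q-1) so
    that model output can be inverse-transformed.
    """

    E0: np.ndarray
    F0: np.ndarray
    x_means: np.ndarray
    x_sds: np.ndarray
    y_means: np.ndarray
    y_sds: np.ndarray
    feature_names: tuple[str, ...] = field(default=())
    response_names: tuple[str, ...] = field(default=())

    @property
    def n_samples(self) -> int:
        return self.E0.shape[0]

    @property
    def n_features(self) -> int:
        return self.E0.shape[1]

    @property
    def n_responses(self) -> int:
        return self.F0.shape[1]

    def subset_features(self, idx: Sequence[int]) -> "StandardizedData":
        idx = np.asarray(idx, dtype=int)
        names = tuple(self.feature_names[i] for i in idx) if self.feature_names else ()
        return StandardizedData(
            E0=self.E0[:, idx],
            F0=self.F0,
            x_means=self.x_means[idx],
            x_sds=self.x_sds[idx],
            y_means=self.y_means,
            y_sds=self.y_sds,
            feature_names=names,
            response_names=self.response_names,
        )

    def transform_features(self, X_new: np.ndarray) -> np.ndarray:
        """Apply the stored feature centering/scaling to new rows."""
        X_new = np.asarray(X_new, dtype=float)
        return (X_new - self.x_means) / self.x_sds


def read_raw_table(path: str, sep: str | None = None) -> pd.DataFrame:
    """Read a CSV/TSV file with a header row; empty cells and 'NA' are missing."""
    return pd.read_csv(
        path,
        sep=sep,
        engine="python" if sep is None else "c",
        na_values=["NA"],
        keep_default_na=True,
    )


def impute_mean(table: pd.DataFrame) -> pd.DataFrame:
    """Replace every missing cell with its column mean over non-missing entries.

    A fully missing column cannot be imputed and raises ``ValueError`` naming
    the offending column.  Non-missing cells are untouched.
    """
    out = table.copy()
    for col in out.columns:
        vals = pd.to_numeric(out[col], errors="coerce")
        if vals.isna().all():
            raise ValueError(f"column {col!r} has no observed values; cannot mean-impute")
        if vals.isna().any():
            vals = vals.fillna(vals.mean())
        out[col] = vals.to_numpy(dtype=float)
    return out


def load_table(path: str, response: str | Sequence[str], sep: str | None = None) -> DataTable:
    """Read, mean-impute, and package a CSV/TSV file as a :class:`DataTable`."""
    return DataTable.from_dataframe(impute_mean(read_raw_table(path, sep=sep)), response)


def _column_stats(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    means = M.mean(axis=0)
    sds = M.std(axis=0, ddof=1)
    return means, sds


def zscore(table: DataTable, drop_constant: bool = True) -> StandardizedData:
    """Standardize features and responses column-wise: (x - mean) / sd.

    Sample standard deviation (divisor q-1) is used.  Zero-variance feature
    columns are dropped with a warning when ``drop_constant`` is set, and
    raise otherwise.  A constant response column always raises — no model can
    be fit to it.
    """
    x_means, x_sds = _column_stats(table.X)
    y_means, y_sds = _column_stats(table.Y)

    const_y = np.flatnonzero(y_sds == 0)
    if const_y.size:
        names = [table.response_names[i] for i in const_y]
        raise ValueError(f"constant response column(s): {names}")

    keep = np.flatnonzero(x_sds > 0)
    dropped = np.flatnonzero(x_sds == 0)
    if dropped.size:
        names = [table.feature_names[i] for i in dropped]
        if not drop_constant:
            raise ValueError(f"constant feature column(s): {names}")
        logger.warning("dropping %d constant feature column(s): %s", len(names), names[:10])
    if keep.size == 0:
        raise ValueError("all feature columns are constant")

    X = table.X[:, keep]
    E0 = (X - x_means[keep]) / x_sds[keep]
    F0 = (table.Y - y_means) / y_sds

    return StandardizedData(
        E0=E0,
        F0=F0,
        x_means=x_means[keep],
        x_sds=x_sds[keep],
        y_means=y_means,
        y_sds=y_sds,
        feature_names=tuple(table.feature_names[i] for i in keep),
        response_names=table.response_names,
    )


def destandardize_predictions(F_hat: np.ndarray, sd: StandardizedData) -> np.ndarray:
    """Map standardized-scale predictions back onto the original response scale."""
    F_hat = np.asarray(F_hat, dtype=float)
    squeeze = F_hat.ndim == 1
    if squeeze:
        F_hat = F_hat[:, None]
    if F_hat.shape[1] != sd.y_sds.shape[0]:
        raise ValueError("prediction column count does not match stored response scales")
    out = F_hat * sd.y_sds + sd.y_means
    return out[:, 0] if squeeze else out
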
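"""Shared regression metrics (internal; re-exported by :mod:`lapls.evaluation`)."""

from __future__ import annotations

import numpy as np

__all__ = ["r_squared", "rmse"]


def r_squared(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Coefficient of determination 1 − SS_res/SS_tot.

    The total sum of squares is taken around the mean of ``y_true`` over the
    evaluated set.  A constant ``y_true`` has no variance to explain and
    raises ``ValueError``.
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred shapes differ")
    if y_true.size < 2:
        raise ValueError("need at least 2 samples")
    ss_tot = float(((y_true - y_true.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise ValueError("y_true is constant; R² undefined")
    ss_res = float(((y_true - y_pred) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Root-mean-square error, in the units of the inputs."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred shapes differ")
    return float(np.sqrt(((y_true - y_pred) ** 2).mean()))
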
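"""Evaluation harness: metrics, repeated 7:3 split comparisons, and the
(k, s) parameter-grid tuning protocol.

The split protocol standardizes on the training rows only and applies the
stored scaling to the held-out rows, so nothing about the test rows can
influence component selection, the λ path, or feature elimination.  Each
repeat uses the same split for every method (paired comparison).  The grid
protocol, in contrast, tunes on the full table, mirroring how the
hyperparameters are chosen before any train/test evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._metrics import r_squared, rmse
from .pipeline import LAPLSConfig, run_lapls
from .pls import fit_pls
from .preprocessing import DataTable, destandardize_predictions, zscore

logger = logging.getLogger(__name__)

__all__ = [
    "r_squared",
    "rmse",
    "EvalReport",
    "split_evaluate",
    "GridResult",
    "parameter_grid",
    "DEFAULT_S_GRID",
]

#: The s values swept by the tuning protocol.
DEFAULT_S_GRID = (0.001, 0.005, 0.01, 0.05, 0.1, 0.11, 0.12, 0.13, 0.14, 0.15, 0.20)

METHODS = ("pls", "lasso", "lapls")


@dataclass(frozen=True)
class EvalReport:
    """Per-repeat and mean test-set R²/RMSE for each compared method."""

    per_repeat: pd.DataFrame  # columns: repeat, seed, method, r2, rmse
    ratio: float
    repeats: int
    seeds: tuple[int, ...]

    def mean_r2(self, method: str) -> float:
        sub = self.per_repeat[self.per_repeat["method"] == method]
        return float(sub["r2"].mean())

    def mean_rmse(self, method: str) -> float:
        sub = self.per_repeat[self.per_repeat["method"] == method]
        return float(sub["rmse"].mean())

    def summary(self) -> pd.DataFrame:
        return (
            self.per_repeat.groupby("method")[["r2", "rmse"]]
            .mean()
            .reindex(list(METHODS))
            .reset_index()
        )


def _predict_original_scale(E_test: np.ndarray, W_col: np.ndarray, sd_train) -> np.ndarray:
    pred_std = E_test @ W_col
    return destandardize_predictions(pred_std, sd_train)


def split_evaluate(
    table: DataTable,
    cfg: LAPLSConfig,
    ratio: float = 0.7,
    repeats: int = 10,
    seed: int = 0,
) -> EvalReport:
    """Repeated random train/test evaluation of LAPLS against PLS and lasso.

    For each repeat a seeded random split assigns ``ratio`` of the rows to
    training.  LAPLS selection plus reduced refit, a full PLS model, and a
    zero-initialized lasso over the same λ schedule are all fit on the
    training rows; R² and RMSE are reported on the held-out rows, RMSE on
    the original response scale.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    if repeats < 1:
        raise ValueError("repeats must be at least 1")
    q = table.n_samples
    n_train = int(round(ratio * q))
    if n_train < 2 or q - n_train < 2:
        raise ValueError("both train and test splits need at least 2 samples")

    rows = []
    seeds = tuple(seed + r for r in range(repeats))
    valid = 0
    for rep, rep_seed in enumerate(seeds):
        rng = np.random.default_rng(rep_seed)
        perm = rng.permutation(q)
        train_rows, test_rows = perm[:n_train], perm[n_train:]
        train = table.subset_rows(train_rows)
        y_test = table.Y[test_rows, 0]
        if np.ptp(train.Y[:, 0]) == 0:
            logger.warning("repeat %d: constant training response; skipped", rep)
            continue

        sd_train = zscore(train, drop_constant=True)
        kept = [table.feature_names.index(n) for n in sd_train.feature_names]
        E_test = sd_train.transform_features(table.X[np.ix_(test_rows, kept)])

        preds: dict[str, np.ndarray] = {}

        pls_model = fit_pls(sd_train, max_components=cfg.max_components)
        preds["pls"] = _predict_original_scale(E_test, pls_model.W[:, 0], sd_train)

        _, lasso_res = run_lapls(sd_train, cfg, warm_start=False, refit=False)
        pred_std = E_test[:, lasso_res.gold_indices] @ lasso_res.best_coef
        preds["lasso"] = destandardize_predictions(pred_std, sd_train)

        # the PLS baseline doubles as the warm start for LAPLS
        _, lapls_res = run_lapls(
            sd_train, cfg, warm_start=True, refit=True, warm_coef=pls_model.W[:, 0]
        )
        E_test_gold = E_test[:, lapls_res.gold_indices]
        preds["lapls"] = _predict_original_scale(
            E_test_gold, lapls_res.reduced_model.W[:, 0], sd_train
        )

        for method in METHODS:
            rows.append(
                {
                    "repeat": rep,
                    "seed": rep_seed,
                    "method": method,
                    "r2": r_squared(y_test, preds[method]),
                    "rmse": rmse(y_test, preds[method]),
                }
            )
        valid += 1

    if valid < min(3, repeats):
        raise RuntimeError(f"only {valid} valid repeats; need at least {min(3, repeats)}")
    return EvalReport(
        per_repeat=pd.DataFrame(rows), ratio=ratio, repeats=repeats, seeds=seeds
    )


@dataclass(frozen=True)
class GridResult:
    """Best fitting-data R² per (k, s) cell, plus the argmax cell."""

    table: pd.DataFrame  # index: k, columns: s
    best_k: int
    best_s: float
    best_r2: float


def parameter_grid(
    table: DataTable,
    k_values: Sequence[int] = tuple(range(8, 18)),
    s_values: Sequence[float] = DEFAULT_S_GRID,
    max_iter: int = 25,
    max_components: int | None = None,
) -> GridResult:
    """Sweep (k, s) and record each cell's best trace R² on the full table.

    This mirrors the tuning phase: standardization and fitting use all rows,
    and the winning cell supplies the (k, s) passed on to split evaluation.
    """
    k_values = list(k_values)
    s_values = list(s_values)
    if not k_values or not s_values:
        raise ValueError("k_values and s_values must be non-empty")
    sd = zscore(table, drop_constant=True)
    warm_coef = fit_pls(sd, max_components=max_components).W[:, 0]
    grid = pd.DataFrame(index=pd.Index(k_values, name="k"),
                        columns=pd.Index(s_values, name="s"), dtype=float)
    best = (None, None, -np.inf)
    for k in k_values:
        for s in s_values:
            cfg = LAPLSConfig(k=k, s=s, max_iter=max_iter, max_components=max_components)
            _, res = run_lapls(sd, cfg, refit=False, warm_coef=warm_coef)
            grid.loc[k, s] = res.best_r2
            if res.best_r2 > best[2]:
                best = (k, s, res.best_r2)
            logger.info("grid cell k=%d s=%g -> best r2=%.4f", k, s, res.best_r2)
    return GridResult(table=grid, best_k=int(best[0]), best_s=float(best[1]),
                      best_r2=float(best[2]))
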
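"""The LAPLS outer loop: PLS warm start, exponential λ schedule, iterative
feature elimination, and reduced-model refit.

A PLS fit on the full table supplies the initial coefficient vector.  The
coordinate-descent lasso is then run repeatedly with the geometrically
increasing penalty λ = e^(iter − k); features whose coefficients are driven
exactly to zero are removed permanently, so the surviving set shrinks
monotonically.  The iteration with the best fitting-data R² defines the
"gold standard" subset, which is refit with PLS to give the final, simpler
model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._metrics import r_squared
from .cd import CDState, cd_converge, enforce_l1_budget
from .pls import PLSModel, fit_pls
from .preprocessing import StandardizedData

logger = logging.getLogger(__name__)

__all__ = [
    "LAPLSConfig",
    "TraceRecord",
    "SelectionTrace",
    "SelectionResult",
    "lambda_schedule",
    "run_lapls",
    "refit_reduced",
]


@dataclass(frozen=True)
class LAPLSConfig:
    """Tunable parameters of the selection loop.

    k shifts the λ = e^(iter − k) schedule: larger k means gentler penalties
    for longer (the useful range is roughly 8–17).  s is the L1 budget the
    converged coefficients are rescaled onto.  max_components caps the PLS
    warm start (``None`` = min(q−1, p, 10)).
    """

    k: int = 10
    s: float = 0.1
    max_iter: int = 25
    max_components: int | None = None
    tol: float = 1e-6
    max_sweeps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")
        if self.s <= 0:
            raise ValueError("s must be positive")
        if int(self.k) != self.k:
            raise ValueError("k must be an integer")


@dataclass(frozen=True)
class TraceRecord:
    iteration: int
    lambda_: float
    n_features: int
    features: tuple[str, ...]
    r2: float


@dataclass(frozen=True)
class SelectionTrace:
    """Per-outer-iteration record of the elimination path."""

    records: tuple[TraceRecord, ...]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i: int) -> TraceRecord:
        return self.records[i]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iter": [r.iteration for r in self.records],
                "lambda": [r.lambda_ for r in self.records],
                "n_features": [r.n_features for r in self.records],
                "r2": [r.r2 for r in self.records],
            }
        )


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of a LAPLS run: the gold-standard subset and its refit model."""

    best_iteration: int
    gold_standard: tuple[str, ...]
    gold_indices: np.ndarray
    best_r2: float
    best_coef: np.ndarray = field(repr=False, default=None)
    reduced_model: PLSModel | None = None


def lambda_schedule(iteration: int, k: int) -> float:
    """Penalty weight at an outer iteration: λ = e^(iter − k)."""
    if iteration < 1:
        raise ValueError("iteration index starts at 1")
    return math.exp(iteration - k)


def run_lapls(
    sd: StandardizedData,
    cfg: LAPLSConfig,
    warm_start: bool = True,
    refit: bool = True,
    warm_coef: np.ndarray | None = None,
) -> tuple[SelectionTrace, SelectionResult]:
    """Run the full selection loop on standardized data with one response.

    With ``warm_start=False`` the coordinate descent starts from zeros and
    the run is a plain lasso traced over the same λ schedule — the baseline
    against which the PLS initialization is measured.  ``refit=False`` skips
    the reduced-model PLS refit (the trace and subset are unchanged).
    ``warm_coef`` supplies an already-computed warm-start vector (e.g. when
    sweeping hyperparameters over the same data).
    """
    if sd.n_responses != 1:
        raise ValueError("the selection path requires exactly one response column")
    E0 = sd.E0
    f = sd.F0[:, 0]
    p = sd.n_features
    names = sd.feature_names or tuple(str(j) for j in range(p))

    if warm_coef is not None:
        w = np.asarray(warm_coef, dtype=float).copy()
        if w.shape != (p,):
            raise ValueError("warm_coef length does not match the feature count")
    elif warm_start:
        warm = fit_pls(sd, max_components=cfg.max_components)
        w = warm.W[:, 0].copy()
        logger.info("PLS warm start: m=%d components", warm.m)
    else:
        w = np.zeros(p)

    active = np.arange(p)
    records: list[TraceRecord] = []
    path: list[tuple[np.ndarray, np.ndarray]] = []  # (active indices, coefficients)
    for iteration in range(1, cfg.max_iter + 1):
        lam = lambda_schedule(iteration, cfg.k)
        E_act = E0[:, active]
        state = CDState(w=w, lambda_=lam, s=cfg.s, active=active)
        state = cd_converge(state, E_act, f, tol=cfg.tol, max_sweeps=cfg.max_sweeps)
        state = enforce_l1_budget(state)
        nonzero = state.w != 0.0
        if not nonzero.any():
            if iteration == 1:
                raise ValueError(
                    "all coefficients were eliminated at the first iteration; "
                    "increase k (weaker initial penalty) or s"
                )
            logger.info("iteration %d emptied the active set; stopping", iteration)
            break
        active = active[nonzero]
        w = state.w[nonzero]
        fitted = E0[:, active] @ w
        r2 = r_squared(f, fitted)
        records.append(
            TraceRecord(
                iteration=iteration,
                lambda_=lam,
                n_features=active.size,
                features=tuple(names[j] for j in active),
                r2=r2,
            )
        )
        path.append((active.copy(), w.copy()))
        logger.info(
            "iter %2d: lambda=%.4g features=%d r2=%.4f", iteration, lam, active.size, r2
        )

    trace = SelectionTrace(tuple(records))
    best_idx = max(range(len(records)), key=lambda i: (records[i].r2, -i))
    best = records[best_idx]
    gold_names = best.features
    gold_indices, best_coef = path[best_idx]

    reduced = refit_reduced(sd, gold_indices, cfg) if refit else None
    result = SelectionResult(
        best_iteration=best.iteration,
        gold_standard=gold_names,
        gold_indices=gold_indices,
        best_r2=best.r2,
        best_coef=best_coef,
        reduced_model=reduced,
    )
    return trace, result


def refit_reduced(
    sd: StandardizedData, subset: np.ndarray, cfg: LAPLSConfig
) -> PLSModel:
    """Refit PLS on the selected feature subset only.

    The reduced model is the deliverable: a plain PLS regression on the
    surviving features, with its own component count and Q² sequence.
    """
    subset = np.asarray(subset, dtype=int)
    if subset.size == 0:
        raise ValueError("cannot refit on an empty subset")
    return fit_pls(sd.subset_features(subset), max_components=cfg.max_components)
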
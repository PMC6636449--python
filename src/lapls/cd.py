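"""L1-penalized least squares by cyclic coordinate descent.

The objective is J(w) = Σᵢ(yᵢ − Σⱼ wⱼxᵢⱼ)² + λΣⱼ|wⱼ|.  Setting the
subgradient of a single coordinate to zero gives the soft-threshold update

    wⱼ = (ρⱼ + λ/2)/zⱼ   if ρⱼ < −λ/2
       = 0               if ρⱼ ∈ [−λ/2, λ/2]
       = (ρⱼ − λ/2)/zⱼ   if ρⱼ > λ/2

with ρⱼ the partial-residual correlation and zⱼ the squared column norm.
The λ/2 threshold (rather than λ) follows from the RSS being unscaled; the
dead-zone case assigns an exact floating-point zero, which is what makes
coefficients usable for feature elimination.  After convergence an optional
L1-budget step rescales the solution onto the ball Σ|wⱼ| ≤ s, preserving
the zero pattern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "CDState",
    "objective",
    "rho_z",
    "soft_threshold",
    "soft_threshold_update",
    "cd_converge",
    "enforce_l1_budget",
]


@dataclass(frozen=True)
class CDState:
    """Coordinate-descent solver state over the current active features.

    ``active`` keeps the original-feature positions the columns of the
    working design correspond to, so the outer elimination loop can track
    survivors across iterations.
    """

    w: np.ndarray
    lambda_: float
    s: float
    active: np.ndarray
    sweeps: int = 0
    converged: bool = False

    def __post_init__(self) -> None:
        if self.lambda_ < 0:
            raise ValueError("lambda_ must be nonnegative")
        if self.s <= 0:
            raise ValueError("s must be positive")
        object.__setattr__(self, "w", np.asarray(self.w, dtype=float).copy())
        active = np.asarray(self.active, dtype=int)
        if len(np.unique(active)) != active.size:
            raise ValueError("active indices must be unique")
        object.__setattr__(self, "active", active)


def objective(w: np.ndarray, E: np.ndarray, f: np.ndarray, lambda_: float) -> float:
    """Penalized residual sum of squares Σ(y − Ew)² + λΣ|w|."""
    resid = np.asarray(f, dtype=float).ravel() - np.asarray(E, dtype=float) @ w
    return float(resid @ resid + lambda_ * np.abs(w).sum())


def rho_z(j: int, w: np.ndarray, E: np.ndarray, f: np.ndarray) -> tuple[float, float]:
    """Partial-residual correlation ρⱼ = xⱼ·(y − Σ_{k≠j} w_k x_k) and zⱼ = ‖xⱼ‖²."""
    col = E[:, j]
    z_j = float(col @ col)
    if z_j == 0.0:
        raise ValueError(f"column {j} is all zero; drop degenerate columns upstream")
    partial_resid = f - E @ w + w[j] * col
    return float(col @ partial_resid), z_j


def soft_threshold(rho_j: float, z_j: float, lambda_: float) -> float:
    """The single-coordinate minimizer of the penalized objective."""
    half = lambda_ / 2.0
    if rho_j > half:
        return (rho_j - half) / z_j
    if rho_j < -half:
        return (rho_j + half) / z_j
    return 0.0  # closed interval: boundary ties land exactly at zero


def soft_threshold_update(
    j: int, state: CDState, E: np.ndarray, f: np.ndarray
) -> float:
    """Optimal wⱼ holding all other coordinates of ``state.w`` fixed."""
    rho_j, z_j = rho_z(j, state.w, E, f)
    return soft_threshold(rho_j, z_j, state.lambda_)


def _run_sweeps(E, f, w, z, half, tol, max_sweeps):
    """Cyclic soft-threshold sweeps with residual updates; pure-Python kernel."""
    resid = f - E @ w
    p = w.size
    converged = False
    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        max_delta = 0.0
        for j in range(p):
            col = E[:, j]
            w_old = w[j]
            rho_j = col @ resid + w_old * z[j]
            if rho_j > half:
                w_new = (rho_j - half) / z[j]
            elif rho_j < -half:
                w_new = (rho_j + half) / z[j]
            else:
                w_new = 0.0
            if w_new != w_old:
                resid += (w_old - w_new) * col
                w[j] = w_new
                delta = abs(w_new - w_old)
                if delta > max_delta:
                    max_delta = delta
        if max_delta < tol:
            converged = True
            break
    return sweeps, converged


_run_sweeps_py = _run_sweeps
try:  # the jitted kernel is a drop-in; results are bit-identical
    from numba import njit

    _run_sweeps = njit(cache=True)(_run_sweeps)
except ImportError:  # pragma: no cover - numba is an optional accelerator
    pass


def cd_converge(
    state: CDState,
    E: np.ndarray,
    f: np.ndarray,
    tol: float = 1e-6,
    max_sweeps: int = 1000,
    check_monotone: bool = False,
) -> CDState:
    """Cycle coordinates in ascending order until the largest coefficient
    change in a full sweep drops below ``tol``.

    The objective is convex and separable in the penalty, so cyclic descent
    converges to the global minimum; each sweep can only decrease J(w)
    (assertable with ``check_monotone``, which also forces the pure-Python
    kernel).  Runs are deterministic: no coordinate randomization.
    """
    E = np.asfortranarray(E, dtype=float)
    f = np.ascontiguousarray(np.asarray(f, dtype=float).ravel())
    w = state.w.copy()
    z = np.einsum("ij,ij->j", E, E)
    if np.any(z == 0.0):
        bad = int(np.flatnonzero(z == 0.0)[0])
        raise ValueError(f"column {bad} is all zero; drop degenerate columns upstream")
    half = state.lambda_ / 2.0

    if check_monotone:
        prev_obj = objective(w, E, f, state.lambda_)
        converged = False
        sweeps_total = 0
        for _ in range(max_sweeps):
            n_sw, converged = _run_sweeps_py(E, f, w, z, half, tol, 1)
            sweeps_total += n_sw
            obj = objective(w, E, f, state.lambda_)
            assert obj <= prev_obj + 1e-9, "objective increased across a sweep"
            prev_obj = obj
            if converged:
                break
        sweeps = sweeps_total
    else:
        sweeps, converged = _run_sweeps(E, f, w, z, half, float(tol), int(max_sweeps))
    logger.debug(
        "cd: sweeps=%d converged=%s active=%d", sweeps, converged, int((w != 0).sum())
    )
    if not converged:
        logger.warning("coordinate descent hit max_sweeps=%d without converging", max_sweeps)
    return replace(state, w=w, sweeps=sweeps, converged=converged)


def enforce_l1_budget(state: CDState) -> CDState:
    """Rescale onto the L1 ball Σ|wⱼ| ≤ s; the zero pattern is unchanged."""
    total = float(np.abs(state.w).sum())
    if total <= state.s:
        return state
    return replace(state, w=state.w * (state.s / total))
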
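"""Partial least squares core: latent-variable extraction (NIPALS-style),
deflation, leave-one-out cross-validity (Q²) stopping, and back-mapping of
component loadings to a per-feature coefficient vector.

Each component consists of unit weight vectors ``o`` (features) and ``c``
(responses) chosen to maximize Cov(E·o, F·c); ``o`` is the dominant
eigenvector of EᵀFFᵀE, which we obtain from the singular decomposition of
EᵀF to avoid squaring the condition number.  After extracting a component
its rank-one contribution is subtracted (deflation) and the next component
is drawn from the residuals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .preprocessing import StandardizedData

__all__ = [
    "LatentComponent",
    "PLSModel",
    "extract_component",
    "deflate",
    "cross_validity",
    "coefficient_backmap",
    "fit_pls",
    "DEFAULT_Q2_THRESHOLD",
]

#: A component is retained while its cross-validity Q² stays at or above this.
DEFAULT_Q2_THRESHOLD = 0.0975

_ZERO_TOL = 1e-12


@dataclass(frozen=True)
class LatentComponent:
    """One PLS component: weights, scores, and loadings.

    ``t = E·o`` and ``u = F·c`` for the (deflated) matrices at extraction
    time; ``p_load = Eᵀt/‖t‖²`` and ``r_load = Fᵀt/‖t‖²`` are the loadings
    used for deflation and regression.
    """

    o: np.ndarray
    c: np.ndarray
    t: np.ndarray
    u: np.ndarray
    p_load: np.ndarray
    r_load: np.ndarray


@dataclass(frozen=True)
class PLSModel:
    """A fitted PLS regression on standardized data.

    ``W`` (p_active × L) reproduces the cumulative component fit as a linear
    map of the standardized features: E0 @ W == Σ_h t_h r_hᵀ.
    """

    components: tuple[LatentComponent, ...]
    m: int
    q2: tuple[float, ...]
    W: np.ndarray
    residual_F: np.ndarray
    feature_names: tuple[str, ...] = ()
    response_names: tuple[str, ...] = ()

    def predict(self, E_new: np.ndarray) -> np.ndarray:
        """Standardized-scale predictions for standardized feature rows."""
        return np.asarray(E_new, dtype=float) @ self.W

    def summary(self) -> dict:
        """Plain-JSON model summary: m, Q² sequence, named coefficients."""
        coefs = {}
        names = self.feature_names or tuple(str(j) for j in range(self.W.shape[0]))
        for j, name in enumerate(names):
            coefs[name] = self.W[j].tolist() if self.W.shape[1] > 1 else float(self.W[j, 0])
        return {"m": self.m, "q2": list(self.q2), "coefficients": coefs}


def _fix_sign(v: np.ndarray) -> float:
    """Return the sign that makes the first non-negligible entry positive."""
    nz = np.flatnonzero(np.abs(v) > _ZERO_TOL * max(1.0, float(np.abs(v).max())))
    if nz.size == 0:
        return 1.0
    return 1.0 if v[nz[0]] > 0 else -1.0


def extract_component(E: np.ndarray, F: np.ndarray) -> LatentComponent:
    """Extract the dominant covariance direction between E and F.

    The feature weight ``o`` is the top left singular vector of EᵀF (equal to
    the dominant eigenvector of EᵀFFᵀE); the response weight ``c`` is the top
    right singular vector.  Both are sign-normalized so the first nonzero
    entry is positive, making extraction deterministic.
    """
    E = np.asarray(E, dtype=float)
    F = np.asarray(F, dtype=float)
    if not np.abs(E).max() > _ZERO_TOL or not np.abs(F).max() > _ZERO_TOL:
        raise ValueError("no remaining variation in E or F")
    M = E.T @ F  # p × L cross-covariance (up to scale)
    if not np.abs(M).max() > 0:
        raise ValueError("no remaining variation: EᵀF is zero")
    U, _, Vt = np.linalg.svd(M, full_matrices=False)
    o = U[:, 0] * _fix_sign(U[:, 0])
    c = Vt[0] * _fix_sign(Vt[0])
    t = E @ o
    u = F @ c
    tt = float(t @ t)
    if tt <= _ZERO_TOL:
        raise ValueError("degenerate score vector; no remaining variation")
    p_load = E.T @ t / tt
    r_load = F.T @ t / tt
    return LatentComponent(o=o, c=c, t=t, u=u, p_load=p_load, r_load=r_load)


def deflate(
    E: np.ndarray, F: np.ndarray, comp: LatentComponent
) -> tuple[np.ndarray, np.ndarray]:
    """Subtract the component's rank-one contribution from both matrices."""
    E_next = E - np.outer(comp.t, comp.p_load)
    F_next = F - np.outer(comp.t, comp.r_load)
    return E_next, F_next


def _extract_sequence(E0: np.ndarray, F0: np.ndarray, m: int) -> list[LatentComponent]:
    """Extract up to m components with deflation, stopping if variation runs out."""
    comps: list[LatentComponent] = []
    E, F = E0, F0
    for _ in range(m):
        try:
            comp = extract_component(E, F)
        except ValueError:
            break
        comps.append(comp)
        E, F = deflate(E, F, comp)
    return comps


def _fitted_from_components(comps: list[LatentComponent], L: int, q: int) -> np.ndarray:
    fitted = np.zeros((q, L))
    for comp in comps:
        fitted += np.outer(comp.t, comp.r_load)
    return fitted


def coefficient_backmap(components, L: int | None = None) -> np.ndarray:
    """Express the cumulative component fit as per-feature coefficients.

    With O, P stacking the weight and loading vectors column-wise and R
    stacking the response loadings row-wise, W = O (PᵀO)⁻¹ R satisfies
    E0 @ W == Σ_h t_h r_hᵀ.
    """
    components = list(components)
    if not components:
        raise ValueError("need at least one component")
    O = np.column_stack([comp.o for comp in components])
    P = np.column_stack([comp.p_load for comp in components])
    R = np.vstack([comp.r_load for comp in components])
    PtO = P.T @ O
    # PᵀO is unit lower triangular for genuinely extracted components; a
    # singular matrix here signals corrupted input.
    if abs(float(np.linalg.det(PtO))) < 1e-12:
        raise ValueError("PᵀO is singular; components were not extracted by deflation")
    return O @ np.linalg.solve(PtO, R)


def cross_validity(E0: np.ndarray, F0: np.ndarray, h: int) -> float:
    """Leave-one-out cross-validity Q² of adding component h (h ≥ 2).

    Q²_h = 1 − PRESS_h / SS_{h−1}: the numerator sums squared errors of
    h-component predictions for each held-out sample (model refit on the
    other q−1 rows, reusing the global standardization); the denominator
    sums squared residuals of the (h−1)-component fit on all samples.
    Returns ``-inf`` when the (h−1)-component fit is already perfect.
    """
    E0 = np.asarray(E0, dtype=float)
    F0 = np.asarray(F0, dtype=float)
    if h < 2:
        raise ValueError("cross-validity is defined for component index h >= 2")
    q, L = F0.shape
    if q < 3:
        raise ValueError("need at least 3 samples for leave-one-out cross-validity")

    full_prev = _extract_sequence(E0, F0, h - 1)
    fitted_prev = _fitted_from_components(full_prev, L, q)
    denom = float(((F0 - fitted_prev) ** 2).sum())
    if denom < _ZERO_TOL:
        return -math.inf

    press = 0.0
    idx = np.arange(q)
    for i in range(q):
        mask = idx != i
        comps_i = _extract_sequence(E0[mask], F0[mask], h)
        W_i = coefficient_backmap(comps_i)
        pred_i = E0[i] @ W_i
        press += float(((F0[i] - pred_i) ** 2).sum())
    return 1.0 - press / denom


def fit_pls(
    sd: StandardizedData,
    max_components: int | None = None,
    q2_threshold: float = DEFAULT_Q2_THRESHOLD,
) -> PLSModel:
    """Fit PLS with sequential extraction and Q² stopping.

    The first component is always retained; component h ≥ 2 is retained only
    while Q²_h ≥ ``q2_threshold``.  Pass ``q2_threshold=-inf`` to keep all
    components up to ``max_components`` (the least-squares limit).  When
    ``max_components`` is None the cap is min(q−1, p, 10): the Q² rule almost
    always stops well before ten components, and the cap bounds the cost of
    the leave-one-out refits on wide tables.
    """
    E0, F0 = sd.E0, sd.F0
    q, p = E0.shape
    L = F0.shape[1]
    cap = min(q - 1, p)
    if max_components is not None:
        cap = min(cap, int(max_components))
    else:
        cap = min(cap, 10)
    if cap < 1:
        raise ValueError("max_components must allow at least one component")

    comps: list[LatentComponent] = []
    q2_seq: list[float] = []
    E, F = E0, F0
    first = extract_component(E, F)  # propagate "no variation" errors
    comps.append(first)
    E, F = deflate(E, F, first)

    skip_q2 = math.isinf(q2_threshold) and q2_threshold < 0
    while len(comps) < cap:
        h = len(comps) + 1
        if not skip_q2:
            if q < 3:
                break
            q2_h = cross_validity(E0, F0, h)
            q2_seq.append(q2_h)
            if q2_h < q2_threshold:
                break
        try:
            comp = extract_component(E, F)
        except ValueError:
            if not skip_q2:
                q2_seq.pop()
            break
        comps.append(comp)
        E, F = deflate(E, F, comp)

    W = coefficient_backmap(comps)
    return PLSModel(
        components=tuple(comps),
        m=len(comps),
        q2=tuple(q2_seq),
        W=W,
        residual_F=F,
        feature_names=sd.feature_names,
        response_names=sd.response_names,
    )
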
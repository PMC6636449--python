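"""Synthetic multicollinear regression tables with known sparse support.

Features are drawn from a zero-mean Gaussian with block compound-symmetry
correlation: within a block every pair of features has correlation
``block_corr``, and blocks are independent.  This is the simplest structure
that reproduces the failure mode the selection method targets — groups of
strongly collinear measurements (e.g. co-eluting mass-spectrometry peaks)
of which only a few actually drive the response.  The response is a sparse
linear combination of the designated support features plus Gaussian noise.

``PRESETS`` provides desk-scale shapes mimicking typical metabolomic and
public regression tables: a wide p >> n table, a tiny p < n table, and a
long n >> p table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocessing import DataTable

__all__ = ["SyntheticSpec", "generate", "make_missing", "PRESETS", "preset_spec"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic table.

    Defaults give the benchmark used throughout the test-suite: 200 samples,
    50 features in five blocks of ten at within-block correlation 0.5, five
    true predictors (one per block) with coefficients of magnitude >= 1, and
    response noise with standard deviation 0.5.
    """

    n: int = 200
    p: int = 50
    support: tuple[int, ...] = (0, 10, 20, 30, 40)
    coefs: tuple[float, ...] = (1.5, -2.0, 1.0, 2.5, -1.5)
    block_corr: float = 0.5
    block_size: int = 10
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.block_corr < 1:
            raise ValueError("block_corr must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if len(self.support) < 1:
            raise ValueError("support must contain at least one feature")
        if len(self.support) != len(self.coefs):
            raise ValueError("support and coefs lengths differ")
        if any(j < 0 or j >= self.p for j in self.support):
            raise ValueError("support indices out of range")
        if len(set(self.support)) != len(self.support):
            raise ValueError("support indices must be unique")
        if self.block_size < 1:
            raise ValueError("block_size must be at least 1")


def generate(spec: SyntheticSpec) -> DataTable:
    """Draw one table: X block-correlated Gaussian, y sparse-linear + noise.

    Within a block, X_j = sqrt(rho)·g + sqrt(1−rho)·e_j with a shared factor
    g per block, so every within-block pair has correlation exactly rho and
    the implied covariance is positive definite for rho < 1.
    """
    rng = np.random.default_rng(spec.seed)
    X = np.empty((spec.n, spec.p))
    rho = spec.block_corr
    for start in range(0, spec.p, spec.block_size):
        width = min(spec.block_size, spec.p - start)
        g = rng.standard_normal((spec.n, 1))
        eps = rng.standard_normal((spec.n, width))
        X[:, start : start + width] = np.sqrt(rho) * g + np.sqrt(1.0 - rho) * eps
    y = X[:, list(spec.support)] @ np.asarray(spec.coefs, dtype=float)
    if spec.noise_sd > 0:
        y = y + spec.noise_sd * rng.standard_normal(spec.n)
    width = len(str(spec.p))
    names = tuple(f"x{j + 1:0{width}d}" for j in range(spec.p))
    return DataTable(X=X, Y=y[:, None], feature_names=names, response_names=("y",))


def make_missing(table: DataTable, frac: float, seed: int = 0) -> pd.DataFrame:
    """Knock out a random ``frac`` of feature cells (never a whole column).

    Returns a DataFrame (features + response) with NaN holes, ready for
    mean imputation.
    """
    if not 0 <= frac < 1:
        raise ValueError("frac must be in [0, 1)")
    df = table.to_dataframe()
    if frac == 0:
        return df
    rng = np.random.default_rng(seed)
    q, p = table.X.shape
    mask = rng.random((q, p)) < frac
    # a fully-missing column cannot be imputed; uncover one random cell
    for j in np.flatnonzero(mask.all(axis=0)):
        mask[rng.integers(q), j] = False
    X = table.X.copy()
    X[mask] = np.nan
    for j, name in enumerate(table.feature_names):
        df[name] = X[:, j]
    return df


def _spread_support(p: int, block_size: int, k: int) -> tuple[int, ...]:
    """First feature of each of the first k blocks."""
    return tuple((i * block_size) % p for i in range(k))


#: Desk-scale shapes echoing common regression-table regimes.
PRESETS: dict[str, SyntheticSpec] = {
    # wide p >> n, strongly collinear blocks (metabolomic feature table shape)
    "wyhxb-like": SyntheticSpec(
        n=54, p=798, block_size=20, block_corr=0.7,
        support=_spread_support(798, 20, 10),
        coefs=(1.5, -2.0, 1.0, 2.5, -1.5, 2.0, -1.0, 1.5, -2.5, 1.0),
        noise_sd=0.5, seed=0,
    ),
    # tiny table, p < n
    "dcqt-like": SyntheticSpec(
        n=10, p=9, block_size=3, block_corr=0.6,
        support=(0, 3, 6), coefs=(1.5, -2.0, 1.0),
        noise_sd=0.1, seed=0,
    ),
    # long n >> p
    "crime-like": SyntheticSpec(
        n=1994, p=127, block_size=8, block_corr=0.5,
        support=_spread_support(127, 8, 10),
        coefs=(1.5, -2.0, 1.0, 2.5, -1.5, 2.0, -1.0, 1.5, -2.5, 1.0),
        noise_sd=1.0, seed=0,
    ),
}


def preset_spec(name: str, seed: int | None = None) -> SyntheticSpec:
    """Look up a preset, optionally replacing its seed."""
    try:
        spec = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None
    if seed is not None:
        spec = SyntheticSpec(**{**spec.__dict__, "seed": seed})
    return spec
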
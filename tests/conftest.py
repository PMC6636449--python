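import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from lapls import DataTable, SyntheticSpec, generate, zscore  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_table(rng, q=20, p=5, L=1, snr=2.0):
    """Small dense regression table with a random linear signal."""
    X = rng.standard_normal((q, p))
    B = rng.standard_normal((p, L))
    Y = X @ B + rng.standard_normal((q, L)) / snr
    return DataTable(
        X=X,
        Y=Y,
        feature_names=tuple(f"x{j}" for j in range(p)),
        response_names=tuple(f"y{j}" for j in range(L)),
    )


@pytest.fixture
def small_table(rng):
    return random_table(rng)


@pytest.fixture
def small_sd(small_table):
    return zscore(small_table)


@pytest.fixture
def benchmark_spec():
    """The default support-recovery benchmark conditions."""
    return SyntheticSpec()


@pytest.fixture
def benchmark_sd(benchmark_spec):
    return zscore(generate(benchmark_spec))
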
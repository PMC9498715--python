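import numpy as np
import pytest

from holopred import SimulationParams, simulate_holoomics
from holopred.kernels import Kernel


def random_psd_kernel(rng, n, kind="GRM"):
    """Well-conditioned random PSD kernel with generic sample IDs."""
    A = rng.standard_normal((n, n + 2))
    K = A @ A.T / (n + 2)
    return Kernel(K, [f"S{i}" for i in range(n)], kind)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_dataset():
    """Shared n=80 synthetic dataset for model-level tests."""
    params = SimulationParams(
        n_samples=80, n_snps=300, n_otus=80,
        var_g=0.4, var_m=0.3, var_gm=0.0, var_e=0.3, seed=1234,
    )
    return simulate_holoomics(params)
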
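import numpy as np
import pytest

from protdeconv import (
    KineticMatrix,
    KineticParams,
    SimConfig,
    sample_kinetic_matrix,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def params():
    return KineticParams(V=0.03, K=0.5, n=1.5, beta=0.2)


@pytest.fixture
def small_km():
    """Deterministic 3 x 2 kinetic panel."""
    cfg = SimConfig(M=3, N=2, seed=7)
    return sample_kinetic_matrix(cfg)


def random_params(rng: np.random.Generator) -> KineticParams:
    return KineticParams(
        V=rng.uniform(0.005, 0.05),
        K=rng.uniform(0.1, 0.9),
        n=rng.uniform(0.5, 3.0),
        beta=rng.uniform(0.0, 0.4),
    )
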
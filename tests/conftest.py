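import numpy as np
import pytest

import ruvnorm as rn


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A small but structurally complete simulated dataset."""
    cfg = rn.SimulationConfig(
        m=24, n=120, n_controls=20, n_replicate_samples=4, seed=7
    )
    return rn.generate_dataset(cfg)


def make_expression(values, prefix_s="s", prefix_g="g"):
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    return rn.ExpressionMatrix(
        values,
        [f"{prefix_s}{i}" for i in range(m)],
        [f"{prefix_g}{j}" for j in range(n)],
    )
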
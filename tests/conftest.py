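import numpy as np
import pytest

from enform import LimitConfig, SimulationConfig, refine_network

# Reduced-scale study conditions shared across comparison tests: five
# replicate seeds per constraint condition at N=50, 50 epochs (the other
# protocol parameters at their reference defaults).
REDUCED = dict(n_nodes=50, n_epochs=50)
SEEDS = (1, 2, 3, 4, 5)


@pytest.fixture(scope="session")
def reduced_limited():
    """Five reduced-scale runs with the weight limit n_sigma=5, alpha=1e-3."""
    return [
        refine_network(
            SimulationConfig(**REDUCED, seed=s, limit=LimitConfig(n_sigma=5, alpha=1e-3))
        )
        for s in SEEDS
    ]


@pytest.fixture(scope="session")
def reduced_nolimit():
    """Five reduced-scale runs without the weight limit (alpha=1e-3)."""
    return [
        refine_network(
            SimulationConfig(**REDUCED, seed=s, limit=LimitConfig(n_sigma=None, alpha=1e-3))
        )
        for s in SEEDS
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
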
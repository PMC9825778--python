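import numpy as np
import pytest

from bmvae.io import MISSING, MutationMatrix
from bmvae.simulate import SimulationConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_ternary(rng) -> MutationMatrix:
    """A 30x12 matrix with ~10% missing entries."""
    values = rng.integers(0, 2, size=(30, 12)).astype(np.int8)
    values[rng.random((30, 12)) < 0.1] = MISSING
    values[0, 0] = 1  # guarantee at least one observed entry
    return MutationMatrix(values)


@pytest.fixture(scope="session")
def noiseless_three_clones() -> "simulate_dataset":
    """120 cells, 3 clearly distinct clones, no noise/missing/doublets."""
    config = SimulationConfig(
        alpha=0.0, beta=0.0, n_cells=120, n_loci=60, n_clones=3,
        missing_rate=0.0, doublet_rate=0.0, seed=5,
    )
    return simulate_dataset(config)


@pytest.fixture(scope="session")
def noisy_small_dataset():
    """300 cells x 120 loci, 4 clones, default noise, with doublets."""
    config = SimulationConfig(
        alpha=0.01, beta=0.3, n_cells=300, n_loci=120, n_clones=4, seed=11,
    )
    return simulate_dataset(config)
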
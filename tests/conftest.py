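import numpy as np
import pytest

from angiopet.config import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_config():
    """A small, fast lattice used by unit tests (not the study resolution)."""
    return SimulationConfig(grid_nodes_per_side=41, angiogenesis_days=5,
                            steps_per_day=40, rng_seed=7)


@pytest.fixture
def tiny_config():
    return SimulationConfig(grid_nodes_per_side=11, angiogenesis_days=1,
                            steps_per_day=10, rng_seed=3)
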
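import numpy as np
import pytest

from fogaging.simulate import SimulationConfig, make_design, simulate_dataset


@pytest.fixture
def design12():
    """The study layout: 2x2 cells, 3 replicates each, 12 samples."""
    return make_design(3)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def default_simulation():
    """One mixed-regime dataset at the default study conditions."""
    config = SimulationConfig(n_features=2000, seed=42)
    expression, design, truth = simulate_dataset(config)
    return config, expression, design, truth
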
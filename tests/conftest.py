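import numpy as np
import pytest

from moltseq.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A compact simulated study shared by read-only tests."""
    return simulate_study(SimulationConfig(seed=42, n_genes=300, n_chroms=3))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
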
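import numpy as np
import pytest

from chromtrace.synthetic_data import SimConfig, simulate_genome


@pytest.fixture(scope="session")
def default_sim():
    """One deterministic default-condition simulation shared across tests."""
    cfg = SimConfig(seed=7)
    genome, truth = simulate_genome(cfg)
    return cfg, genome, truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)
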
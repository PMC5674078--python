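import numpy as np
import pytest

from thzchem import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def small_dataset():
    """A matched descriptor/spectra dataset at the study size (n=27, seed 1)."""
    return simulate_dataset(SimConfig(n_samples=27, seed=1, mp_link_strength=0.9))


@pytest.fixture(scope="session")
def tiny_dataset():
    """A fast dataset for bookkeeping-style tests (n=12, coarse grid)."""
    cfg = SimConfig(n_samples=12, seed=7, n_points=201, mp_link_strength=0.9)
    return simulate_dataset(cfg)
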
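import numpy as np
import pandas as pd
import pytest

from auxmic import SimulationConfig, simulate_dataset
from auxmic.mic import MicEstimator


@pytest.fixture(scope="session")
def central_config():
    """A representative middle-of-the-grid condition."""
    return SimulationConfig(n_subjects=2000, seed=42)


@pytest.fixture(scope="session")
def central_panel():
    """Large panel (latent + observed) for moment and calibration checks."""
    return simulate_dataset(SimulationConfig(n_subjects=50_000, seed=1234))


@pytest.fixture(scope="session")
def observed_2000(central_config):
    return simulate_dataset(central_config).observed_frame()


@pytest.fixture(scope="session")
def population_fit_c():
    """Model C fitted at population scale on the central condition."""
    cfg = SimulationConfig(n_subjects=100_000, seed=7)
    obs = simulate_dataset(cfg, include_latent=False).observed_frame()
    est = MicEstimator(model="C").fit(obs)
    assert est.converged_
    return cfg, est
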
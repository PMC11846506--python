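import numpy as np
import pytest

from gamvar import synthetic_data as syn
from gamvar.model import build_model_data


@pytest.fixture(scope="session")
def small_dataset():
    """4 species x 72 months synthetic community with known truth."""
    cfg = syn.SimulationConfig(n_species=4, n_months=72, seed=42)
    params, cov, cts = syn.simulate_dataset(cfg)
    return params, cov, cts


@pytest.fixture(scope="session")
def small_model_data(small_dataset):
    _, cov, cts = small_dataset
    return build_model_data(cts, cov)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)
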
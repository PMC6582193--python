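import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import hoirt

settings.register_profile(
    "ci", max_examples=50, deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_design():
    """Benchmark design scaled to 60 persons/group for fast fits."""
    return hoirt.benchmark_design(60, seed=101)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_design):
    rng = np.random.default_rng(101)
    data, traits = hoirt.simulate_dataset(tiny_design, rng)
    return data, traits


@pytest.fixture(scope="session")
def small_fit(tiny_design, tiny_dataset):
    """A short but real MCMC fit shared by diagnostics/structure tests."""
    data, _ = tiny_dataset
    cfg = hoirt.MCMCConfig(n_chains=2, n_iter=700, burn_in=300, seed=202)
    draws = hoirt.run_chains(data, tiny_design.items, tiny_design.dims,
                             config=cfg)
    return draws, data
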
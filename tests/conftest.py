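import numpy as np
import pytest
from hypothesis import settings

from mcia import SimConfig, make_observed_summary, simulate_experiment

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """A reduced experiment for pipeline tests: 6 participants, 2 blocks."""
    return SimConfig(n_participants=6, n_blocks=2, seed=7)


@pytest.fixture(scope="session")
def small_experiment(small_config):
    trials, truth = simulate_experiment(small_config)
    return trials, truth


@pytest.fixture(scope="session")
def small_summary(small_config):
    summary, kept, truth = make_observed_summary(small_config)
    return summary, kept, truth


@pytest.fixture(scope="session")
def full_summary():
    """A full-size experiment (19 participants x 4 blocks) at the defaults."""
    summary, kept, truth = make_observed_summary(SimConfig(seed=7))
    return summary, kept, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
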
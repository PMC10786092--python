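import numpy as np
import pytest
from hypothesis import settings

import rsamediate as rm

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def small_config():
    """A fast, low-dimensional stated world for unit tests."""
    return rm.SimulationConfig(
        n_channels=8,
        sampling_rate_hz=100.0,
        trials_per_condition=8,
        noise_variance_uv2=4.0,
        seed=11,
    )


@pytest.fixture
def default_config():
    return rm.SimulationConfig(seed=11)


@pytest.fixture
def small_epochs(small_config):
    return rm.simulate_participant_eeg(small_config, race_strength=1.0, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
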
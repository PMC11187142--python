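import numpy as np
import pytest

from ripplecue import SimParams
from ripplecue.synth import make_task_dataset


@pytest.fixture(scope="session")
def small_params() -> SimParams:
    """Desk-scale iEEG-like study: 500 Hz, 8 channels, 10 trials/class."""
    return SimParams(fs=500.0, n_channels=8, n_trials=10, seed=11)


@pytest.fixture(scope="session")
def task_dataset(small_params):
    return make_task_dataset(small_params)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
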
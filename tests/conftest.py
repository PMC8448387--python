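import warnings

import numpy as np
import pytest

from calwave.config import SimulationConfig
from calwave.synthetic import simulate_movie, truth_frame


@pytest.fixture(scope="session")
def small_config():
    """A fast movie config that keeps the default acquisition protocol."""
    return SimulationConfig(height=96, width=96, pixel_size=2.5, n_cells=40,
                            seed=7)


@pytest.fixture(scope="session")
def small_movie(small_config):
    movie, truth = simulate_movie(small_config)
    return movie, truth_frame(truth)


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("always")
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
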
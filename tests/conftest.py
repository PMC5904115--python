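import numpy as np
import pytest
from hypothesis import settings

from proscribe import ModelConfig, SlantStimulus

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def config():
    return ModelConfig()


@pytest.fixture
def toy_config():
    """5-unit configuration for brute-force oracle comparisons."""
    return ModelConfig(n_units=5)


@pytest.fixture
def incongruent_stimulus():
    """The behavioural incongruent condition: disparity 20deg, texture 50deg,
    1:4 intensity (1:2 sensitivity) ratio."""
    return SlantStimulus.from_degrees(20.0, 50.0, 1.0, 4.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
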
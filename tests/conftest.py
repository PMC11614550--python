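import numpy as np
import pytest

from betasync import SimulationConfig, synthesize_segment


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig()


@pytest.fixture(scope="session")
def rest_segment(default_config):
    """One simulated 60-s rest segment with spike trains attached."""
    segment, truth = synthesize_segment(default_config, "rest", seed=777)
    return segment, truth
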
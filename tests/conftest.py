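import numpy as np
import pytest

from cogload.simulate import SimulationConfig, simulate_session


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """A desk-scale configuration with every channel present."""
    return SimulationConfig(seed=11, n_participants=3,
                            session_duration_s=40.0)


@pytest.fixture(scope="session")
def small_session(small_cfg):
    """One fully multimodal simulated session plus its ground truth."""
    return simulate_session(small_cfg, 0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
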
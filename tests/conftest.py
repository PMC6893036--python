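import numpy as np
import pytest

from neuroxkit import synth


@pytest.fixture(scope="session")
def light_config():
    """Reduced-rate study configuration used by most integration tests:
    short record, 2 kHz neural channel, sparse decay records."""
    return synth.SessionConfig(duration=120.0, neural_rate=2000.0,
                               bout_rate_per_min=4.0, decay_rate=200.0)


@pytest.fixture(scope="session")
def light_session(light_config):
    return synth.generate_session(light_config, seed=11)


@pytest.fixture(scope="session")
def resp_session():
    """Quiet session with strong respiration-phase PaO2 modulation."""
    cfg = synth.SessionConfig(duration=90.0, neural_rate=2000.0,
                              bout_rate_per_min=0.0,
                              resp_modulation_depth=5.0, decay_rate=1000.0)
    return synth.generate_session(cfg, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
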
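import numpy as np
import pytest

from hlapocket import SimulationConfig, build_pocket_model, make_groove


@pytest.fixture
def config():
    return SimulationConfig(seed=11)


@pytest.fixture
def groove(config):
    return make_groove(config)


@pytest.fixture
def pocket_model(groove):
    return build_pocket_model(groove)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
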
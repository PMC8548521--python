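import numpy as np
import pytest

from apivr.geometry import ArenaConfig
from apivr.protocol import ProtocolConfig


@pytest.fixture
def arena():
    return ArenaConfig()


@pytest.fixture
def protocol():
    return ProtocolConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
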
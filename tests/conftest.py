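import numpy as np
import pytest

from hmgb1smc.fixtures import make_toy_network
from hmgb1smc.hmgb1 import build_hmgb1_network


@pytest.fixture(scope="session")
def hmgb1_network():
    return build_hmgb1_network()


@pytest.fixture()
def decay_network():
    return make_toy_network("decay", d=0.01, A0=1000)


@pytest.fixture()
def birth_death_network():
    return make_toy_network("birth_death", k=50, d=0.1)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
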
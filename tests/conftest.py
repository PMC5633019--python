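import numpy as np
import pytest

from avinet import EnvironmentParams, NetworkParams, init_weights
from avinet.bayes import template_matrix


@pytest.fixture(scope="session")
def env():
    return EnvironmentParams()

@pytest.fixture(scope="session")
def net_params():
    return NetworkParams()


@pytest.fixture(scope="session")
def untrained_weights():
    return init_weights()


@pytest.fixture(scope="session")
def template_weights(env):
    """Weights whose RFs equal the noiseless stimulus templates — the
    analytic fixed point of the RF learning rule under a flat position
    prior.  A convenient stand-in for a fully trained network in tests
    that only need mature receptive fields."""
    w = init_weights()
    w.rf_a = template_matrix("A", env)
    w.rf_v = template_matrix("V", env)
    return w


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
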
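import numpy as np
import pytest

from avdflux.networks import central_network, toy_cleave, toy_linear, toy_split_recombine


@pytest.fixture(scope="session")
def central_model():
    return central_network()


@pytest.fixture(scope="session")
def toy_models():
    return {
        "linear": toy_linear(),
        "cleave": toy_cleave(),
        "split_recombine": toy_split_recombine(),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)
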
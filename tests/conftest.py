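import numpy as np
import pytest

from sidestep import ModelParameters, make_initial_state


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def initial_state(params):
    return make_initial_state(params)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20170607)
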
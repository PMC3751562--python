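import numpy as np
import pytest
from hypothesis import settings

from pancfate.model import ModelParams
from pancfate.tissue import make_triangle3

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def p():
    """Reference parameter set."""
    return ModelParams()


@pytest.fixture()
def triangle():
    return make_triangle3()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
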
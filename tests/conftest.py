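import numpy as np
import pytest

from sinusim.params import load_params
from sinusim.transport import SinusoidModel


@pytest.fixture(scope="session")
def params():
    return load_params()


@pytest.fixture(scope="session")
def model(params):
    return SinusoidModel(params)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160915)
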
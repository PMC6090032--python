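import numpy as np
import pytest

from rdnacn.methylation_index import default_retention
from rdnacn.repeat_model import build_default_unit


@pytest.fixture(scope="session")
def unit():
    return build_default_unit()


@pytest.fixture(scope="session")
def retention(unit):
    # calibrated once per session; deterministic
    return default_retention(unit)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
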
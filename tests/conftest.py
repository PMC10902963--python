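import numpy as np
import pytest

from orthoplan.cephalometry import default_reference_intervals
from orthoplan.cohort import make_template


@pytest.fixture(scope="session")
def template():
    return make_template()


@pytest.fixture(scope="session")
def intervals():
    return default_reference_intervals()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
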
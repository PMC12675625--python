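import numpy as np
import pytest

from glymphpipe.phantom import ConditionParams, make_phantom
from glymphpipe.scheme import default_scheme


@pytest.fixture(scope="session")
def scheme():
    """The study acquisition protocol (106 volumes)."""
    return default_scheme()

@pytest.fixture(scope="session")
def low_b_scheme(scheme):
    """b = 0 and b = 700 volumes only (the strict low-b tensor subset)."""
    return scheme.subset(scheme.bvals <= 700)

@pytest.fixture(scope="session")
def control_phantom():
    return make_phantom((20, 24, 20), condition=ConditionParams.control(),
                        seed=0)

@pytest.fixture(scope="session")
def patient_phantom():
    return make_phantom((20, 24, 20), condition=ConditionParams.patient(),
                        seed=0)

@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
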
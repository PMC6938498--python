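import numpy as np
import pytest

from tactoidmc.geometry import make_spindle


@pytest.fixture(scope="session")
def spindle90():
    """The smallest container of the size sweep: Ly/L = 4.5 at aspect 1.5."""
    return make_spindle(90.0, 1.5, 6.0)


@pytest.fixture(scope="session")
def circle90():
    return make_spindle(90.0, 1.0, 6.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
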
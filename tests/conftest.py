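import numpy as np
import pytest

from fragmeta import TorusGrid, make_fragmented, make_homogeneous


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def grid32():
    return TorusGrid(32)


@pytest.fixture(scope="session")
def fragmented60():
    """One highly fragmented 60x60 landscape shared across tests."""
    return make_fragmented(60, 3.0, 1.1, np.random.default_rng(11))


@pytest.fixture(scope="session")
def homogeneous60():
    return make_homogeneous(60)
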
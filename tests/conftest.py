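import numpy as np
import pytest

from scnsurf.mesh import build_icosphere, seed_patch


@pytest.fixture(scope="session")
def ico2():
    return build_icosphere(2, radius=70.0)


@pytest.fixture(scope="session")
def ico3():
    return build_icosphere(3, radius=70.0)


@pytest.fixture(scope="session")
def ico4():
    return build_icosphere(4, radius=70.0)


@pytest.fixture(scope="session")
def ico3_seed(ico3):
    return seed_patch(ico3, 0, 15.0, "CAL_L")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
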
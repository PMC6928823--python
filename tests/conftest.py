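import numpy as np
import pytest

from cacomplex.bk import BKRateParams
from cacomplex.cav import CaVParams
from cacomplex.exocytosis import GranuleParams
from cacomplex.nanodomain import default_nanodomain_params


@pytest.fixture(scope="session")
def nano():
    return default_nanodomain_params()


@pytest.fixture(scope="session")
def cavp():
    return CaVParams()


@pytest.fixture(scope="session")
def bkp():
    return BKRateParams()


@pytest.fixture(scope="session")
def granule():
    return GranuleParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
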
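import numpy as np
import pytest
from hypothesis import settings

from splinodule.filterbank import make_filterbank

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=60)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def haar_bank():
    return make_filterbank("haar", 0)


@pytest.fixture(scope="session")
def bior12_bank():
    return make_filterbank("biorthogonal_spline", 1, 2)


@pytest.fixture(scope="session")
def bior32_bank():
    return make_filterbank("biorthogonal_spline", 3, 2)


@pytest.fixture(scope="session")
def semi3_bank():
    return make_filterbank("semiorthogonal_bspline", 3)


@pytest.fixture(scope="session")
def all_banks(haar_bank, bior12_bank, bior32_bank, semi3_bank):
    return [haar_bank, bior12_bank, bior32_bank, semi3_bank]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
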
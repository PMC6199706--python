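import numpy as np
import pytest

from dgrscan.model import SimParams
from dgrscan.simulate import plant_cassette


@pytest.fixture(scope="session")
def planted():
    """A planted DGR genome with exactly 14 adenine mismatches (seed 1)."""
    return plant_cassette(SimParams(seed=1), force_mismatches=14)


@pytest.fixture(scope="session")
def hankyphage():
    from dgrscan.synthetic_refs import synthetic_hankyphage

    return synthetic_hankyphage()


@pytest.fixture(scope="session")
def bpp1():
    from dgrscan.synthetic_refs import synthetic_bpp1

    return synthetic_bpp1()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
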
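import numpy as np
import pytest

from m2rds.lifting import build_cake_wavelets


@pytest.fixture(scope="session")
def wavelets8():
    return build_cake_wavelets(8, 17)


@pytest.fixture(scope="session")
def wavelets16():
    return build_cake_wavelets(16, 33)


@pytest.fixture(scope="session")
def wavelets32():
    return build_cake_wavelets(32, 33)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
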
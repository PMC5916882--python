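import numpy as np
import pytest

from relaxnet import SpinLock, SpinSystem


@pytest.fixture(scope="session")
def spin() -> SpinSystem:
    return SpinSystem()  # 800 MHz, r_NH = 1.02 Å, Δσ = 170 ppm


@pytest.fixture(scope="session")
def lock20() -> SpinLock:
    return SpinLock(20.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
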
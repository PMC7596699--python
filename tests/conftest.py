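import numpy as np
import pytest

from halfcenter import DriveConfig, NetworkConfig, UnitParams
from halfcenter.simulate import integrate


@pytest.fixture(scope="session")
def unit() -> UnitParams:
    return UnitParams()


@pytest.fixture(scope="session")
def single_rg() -> NetworkConfig:
    return NetworkConfig.single_rg()


@pytest.fixture(scope="session")
def bilateral() -> NetworkConfig:
    return NetworkConfig.bilateral(0.4, 0.2)


@pytest.fixture(scope="session")
def bursting_trace(single_rg):
    """One steady single-RG bursting run (drive 0.3), reused across tests."""
    return integrate(single_rg, DriveConfig.symmetric(0.3), duration=30_000.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
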
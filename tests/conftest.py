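import numpy as np
import pytest

from thzpowder import (
    DEFAULT_GEOMETRY,
    LACTOHALE_100,
    LACTOHALE_200,
    LACTOHALE_220,
    ContainerGeometry,
    ScanConfig,
)


@pytest.fixture
def geometry() -> ContainerGeometry:
    return DEFAULT_GEOMETRY


@pytest.fixture(params=["Lactohale 100", "Lactohale 200", "Lactohale 220"])
def material(request):
    return {
        "Lactohale 100": LACTOHALE_100,
        "Lactohale 200": LACTOHALE_200,
        "Lactohale 220": LACTOHALE_220,
    }[request.param]


@pytest.fixture
def lh200():
    return LACTOHALE_200


@pytest.fixture
def locked_scan_config() -> ScanConfig:
    """Nominal acquisition: 15 Hz, 4 rpm — exactly 225 samples/rotation."""
    return ScanConfig(noise_sigma=0.0, seed=0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
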
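import numpy as np
import pytest

from afterimage.colorimetry import DEFAULT_MONITOR, DKLSpace
from afterimage.models import AdaptationConfig, HeringPrototypes
from afterimage.munsell import synthetic_renotation_table


@pytest.fixture(scope="session")
def monitor():
    return DEFAULT_MONITOR


@pytest.fixture(scope="session")
def dkl(monitor):
    return DKLSpace(monitor)


@pytest.fixture(scope="session")
def cfg():
    return AdaptationConfig()


@pytest.fixture(scope="session")
def prototypes():
    # plausible measured unique-hue azimuths in CIELUV
    return HeringPrototypes(red=12.0, yellow=68.0, green=160.0, blue=253.0)


@pytest.fixture(scope="session")
def munsell_table(monitor):
    w = monitor.white
    return synthetic_renotation_table(white_xy=(w.x, w.y))


@pytest.fixture(scope="session")
def random_in_gamut_XYZ(monitor):
    """1000 random in-gamut colours (rendered from random drive values)."""
    rng = np.random.default_rng(12345)
    rgb = rng.uniform(0.05, 1.0, size=(1000, 3))
    return monitor.rgb_to_XYZ(rgb)
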
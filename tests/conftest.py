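import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import infarctmap as im

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

NOISE_FREE = im.TissueStats(
    remote_t1_sd=0.0, infarct_t1_sd=0.0, remote_lge_sd=0.0, infarct_lge_sd=0.0
)


@pytest.fixture(scope="session")
def noise_free_tissue():
    return NOISE_FREE


@pytest.fixture(scope="session")
def mid_geometry():
    return im.default_geometry("mid", pixel_spacing=1.4)


@pytest.fixture(scope="session")
def fine_geometry():
    """Mid-slice geometry at 0.35 mm spacing for sub-pixel accuracy checks."""
    return im.default_geometry("mid", pixel_spacing=0.35)


@pytest.fixture(scope="session")
def noise_free_phantom(mid_geometry):
    return im.make_phantom(
        mid_geometry,
        im.InfarctSpec(center_angle=60, angular_extent=120, transmural_depth=0.8),
        NOISE_FREE,
        seed=11,
    )


@pytest.fixture(scope="session")
def noisy_phantom(mid_geometry):
    return im.make_phantom(
        mid_geometry,
        im.InfarctSpec(center_angle=60, angular_extent=120, transmural_depth=0.8),
        im.TissueStats(),
        seed=12,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
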
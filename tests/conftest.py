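import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from trabmorph import BinaryVolume, ImageVolume, PhantomSpec

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_spec():
    """A small phantom spec used where geometry, not scale, is under test."""
    return PhantomSpec(
        target_bvtv=0.30,
        voi_extent=(3.0, 2.0, 4.0),
        fine_spacing=0.05,
        cortical_plate_thickness=0.4,
        seed=7,
    )


@pytest.fixture()
def flat_volume():
    """A 4-slice volume of zeros on a 0.25 mm grid, handy for ROI geometry."""
    return ImageVolume(np.zeros((4, 16, 16)), spacing=(1.0, 0.25, 0.25))


@pytest.fixture()
def checker_mask(rng):
    """A random ~30% bone mask on an isotropic 0.1 mm grid."""
    return BinaryVolume(rng.random((24, 24, 24)) < 0.3, spacing=(0.1, 0.1, 0.1))
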
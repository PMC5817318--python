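import numpy as np
import pytest

from cbctscatter.geometry import CBCTGeometry
from cbctscatter.phantom import make_cylinder
from cbctscatter.spectrum import EnergySpectrum, make_fixture_spectrum


@pytest.fixture(scope="session")
def spectrum90():
    """Heavily filtered 90 kVp tube spectrum fixture."""
    return make_fixture_spectrum()


@pytest.fixture(scope="session")
def mono60():
    """Monoenergetic 60 keV beam."""
    return EnergySpectrum(np.array([60.0]), np.array([1.0]))


@pytest.fixture(scope="session")
def water_cylinder():
    """100 mm diameter, 100 mm tall water cylinder at 2 mm voxels."""
    return make_cylinder(50.0, 100.0, density=1.0, voxel_size_mm=2.0)


@pytest.fixture(scope="session")
def coarse_geometry():
    """Full-area detector rebinned to 32 x 32 pixels, single view."""
    return CBCTGeometry(detector_pixels=(32, 32), pixel_pitch=0.508 * 480 / 32,
                        view_angles=np.array([0.0]))


@pytest.fixture(scope="session")
def demo_geometry():
    """Scaled-down scan: 36 views, 64 x 48 detector over the full area."""
    return CBCTGeometry(detector_pixels=(64, 48), pixel_pitch=3.81,
                        view_angles=np.arange(36) * 10.0)
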
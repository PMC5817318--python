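import numpy as np
import pytest

from cbctscatter.correction import log_projections
from cbctscatter.fdk import FilterSpec, build_filter, fdk_reconstruct, weight_projection
from cbctscatter.geometry import CBCTGeometry, ProjectionImage
from cbctscatter.materials import get_material, mu_linear
from cbctscatter.metrics import cylinder_cupping
from cbctscatter.phantom import VoxelPhantom, make_cylinder
from cbctscatter.projector import analytic_primary, blank_scan


@pytest.fixture(scope="module")
def fine_geometry():
    """120 views on a 128 x 96 detector: adequate sampling for quantitative
    reconstruction checks."""
    return CBCTGeometry(detector_pixels=(128, 96), pixel_pitch=3.81 / 2,
                        view_angles=np.arange(120) * 3.0)


@pytest.fixture(scope="module")
def cylinder_recon(fine_geometry, mono60, water_cylinder):
    stack = [analytic_primary(water_cylinder, fine_geometry, mono60, a,
                              scale=1e4, supersample=2)
             for a in fine_geometry.view_angles]
    blank = blank_scan(fine_geometry, mono60, scale=1e4)
    logs = log_projections(stack, blank, epsilon_floor=1e-12)
    return fdk_reconstruct(logs, fine_geometry, FilterSpec(cutoff=0.7), 2.0,
                           (64, 64, 64))


class TestWeighting:
    def test_central_pixel_weight_unity(self):
        geo = CBCTGeometry(detector_pixels=(31, 25), pixel_pitch=2.0,
                           view_angles=np.array([0.0]))
        p = np.ones((25, 31))
        w = weight_projection(p, geo)
        assert w[12, 15] == pytest.approx(1.0)

    def test_weight_decreases_off_axis(self):
        geo = CBCTGeometry(detector_pixels=(31, 25), pixel_pitch=2.0,
                           view_angles=np.array([0.0]))
        w = weight_projection(np.ones((25, 31)), geo)
        assert np.all(np.diff(w[12, 15:]) < 0)
        assert np.all(np.diff(w[12:, 15]) < 0)

    def test_corner_weight_closed_form(self):
        geo = CBCTGeometry(detector_pixels=(31, 25), pixel_pitch=2.0,
                           view_angles=np.array([0.0]))
        w = weight_projection(np.ones((25, 31)), geo)
        u = (30 - 15) * 2.0
        v = (24 - 12) * 2.0
        expected = geo.d_sd / np.sqrt(geo.d_sd**2 + u**2 + v**2)
        assert w[24, 30] == pytest.approx(expected, rel=1e-12)


class TestFilter:
    def test_zero_frequency_response_is_zero(self):
        h = build_filter(64, 1.0, FilterSpec(cutoff=0.7))
        assert h[0] == 0.0

    def test_hard_cutoff(self):
        pitch = 0.5
        h = build_filter(128, pitch, FilterSpec(cutoff=0.7))
        f = np.fft.rfftfreq(128, d=pitch)
        f_nyq = 1.0 / (2.0 * pitch)
        assert np.all(h[f > 0.7 * f_nyq + 1e-12] == 0.0)
        assert np.all(h[(f > 0) & (f <= 0.7 * f_nyq)] > 0.0)

    def test_pure_tone_scaled_by_response(self):
        n, pitch = 128, 1.0
        spec = FilterSpec(cutoff=0.7)
        h = build_filter(n, pitch, spec)
        k = 10  # tone index well below cutoff
        x = np.cos(2 * np.pi * k * np.arange(n) / n)
        y = np.fft.irfft(np.fft.rfft(x) * h, n=n)
        np.testing.assert_allclose(y, h[k] * x, atol=1e-12)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            FilterSpec(cutoff=0.0)
        with pytest.raises(ValueError):
            FilterSpec(kind="ramlak")
        with pytest.raises(ValueError):
            build_filter(1, 1.0, FilterSpec())


class TestReconstruction:
    def test_zero_projections_give_zero_volume(self, fine_geometry):
        logs = [ProjectionImage(np.zeros((96, 128)), a)
                for a in fine_geometry.view_angles]
        vol = fdk_reconstruct(logs, fine_geometry, FilterSpec(), 2.0, (32, 32, 32))
        np.testing.assert_array_equal(vol.voxels, 0.0)

    def test_linearity_in_projections(self, mono60, water_cylinder):
        geo = CBCTGeometry(detector_pixels=(64, 48), pixel_pitch=3.81,
                           view_angles=np.arange(24) * 15.0)
        stack = [analytic_primary(water_cylinder, geo, mono60, a, scale=1e4)
                 for a in geo.view_angles]
        blank = blank_scan(geo, mono60, scale=1e4)
        logs = log_projections(stack, blank, epsilon_floor=1e-12)
        doubled = [ProjectionImage(2.0 * p.pixels, p.view_angle) for p in logs]
        v1 = fdk_reconstruct(logs, geo, FilterSpec(), 4.0, (32, 32, 32))
        v2 = fdk_reconstruct(doubled, geo, FilterSpec(), 4.0, (32, 32, 32))
        np.testing.assert_allclose(v2.voxels, 2.0 * v1.voxels, rtol=1e-9, atol=1e-12)

    def test_uniform_cylinder_quantitative(self, cylinder_recon, mono60):
        mu_mm = mu_linear(get_material("soft_tissue"), 60.0, 1.0) / 10.0
        v = cylinder_recon.voxels
        x = (np.arange(64) - 31.5) * 2.0
        r = np.sqrt(x[:, None] ** 2 + x[None, :] ** 2)
        interior = v[:, :, 28:36][r <= 40.0]
        assert interior.mean() == pytest.approx(mu_mm, rel=0.05)
        assert interior.std() / interior.mean() < 0.05

    def test_cylinder_cupping_free(self, cylinder_recon):
        assert abs(cylinder_cupping(cylinder_recon, 50.0)) < 2.0

    def test_axial_symmetry(self, cylinder_recon):
        sl = cylinder_recon.voxels[:, :, 32]
        np.testing.assert_allclose(sl, sl.T, atol=0.05 * sl.max())

    def test_small_sphere_peaks_at_center(self, mono60):
        geo = CBCTGeometry(detector_pixels=(64, 48), pixel_pitch=3.81,
                           view_angles=np.arange(60) * 6.0)
        density = np.zeros((33, 33, 33), dtype=np.float32)
        xs = (np.arange(33) - 16.0) * 2.0
        rr = np.sqrt(xs[:, None, None] ** 2 + xs[None, :, None] ** 2
                     + xs[None, None, :] ** 2)
        density[rr <= 8.0] = 1.0
        ph = VoxelPhantom(density, (2, 2, 2), (-33.0, -33.0, -33.0))
        stack = [analytic_primary(ph, geo, mono60, a, scale=1e4, supersample=2)
                 for a in geo.view_angles]
        blank = blank_scan(geo, mono60, scale=1e4)
        logs = log_projections(stack, blank, epsilon_floor=1e-12)
        vol = fdk_reconstruct(logs, geo, FilterSpec(), 2.0, (33, 33, 33))
        peak = np.unravel_index(np.argmax(vol.voxels), vol.shape)
        assert np.linalg.norm(np.array(peak) - 16.0) <= 2.0

    def test_missing_coverage_rejected(self, mono60):
        geo = CBCTGeometry(detector_pixels=(16, 16), pixel_pitch=8.0,
                           view_angles=np.arange(0.0, 180.0, 10.0))
        logs = [ProjectionImage(np.zeros((16, 16)), a) for a in geo.view_angles]
        with pytest.raises(ValueError, match="coverage"):
            fdk_reconstruct(logs, geo, FilterSpec(), 4.0, (16, 16, 16))
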
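import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

from cbctscatter.geometry import CBCTGeometry
from cbctscatter.materials import get_material, mu_linear
from cbctscatter.mc import (emit_photon, run_projection_mc, sample_compton,
                            sample_rayleigh)
from cbctscatter.phantom import VoxelPhantom
from cbctscatter.projector import expected_primary_counts
from cbctscatter.spectrum import EnergySpectrum

MEC2 = 510.99895


def kn_pdf_unnormalized(ct, e_kev):
    a = e_kev / MEC2
    x = 1.0 / (1.0 + a * (1.0 - ct))  # E'/E
    return x * x * (x + 1.0 / x - (1.0 - ct * ct))


class TestEmission:
    def test_degenerate_cone_is_axial(self, mono60):
        with pytest.warns(UserWarning, match="cone half-angle"):
            geo = CBCTGeometry(detector_pixels=(8, 8), pixel_pitch=4.0,
                               view_angles=np.array([0.0]),
                               cone_half_angle_limit=1e-9)
        _, dirs, _ = emit_photon(geo, mono60, n=200, seed=0)
        np.testing.assert_allclose(dirs @ np.array([1.0, 0, 0]), 1.0, atol=1e-6)

    def test_cone_support_and_mean_direction(self, spectrum90, coarse_geometry):
        _, dirs, energies = emit_photon(coarse_geometry, spectrum90, n=100_000, seed=1)
        cos_t = dirs @ np.array([1.0, 0, 0])
        assert np.all(cos_t >= np.cos(np.radians(14.0)) - 1e-12)
        # transverse components average to zero within 3 sigma
        for k in (1, 2):
            assert abs(dirs[:, k].mean()) < 3 * dirs[:, k].std() / np.sqrt(len(dirs))
        assert np.all(energies >= spectrum90.energy_bins[0])

    def test_polar_angle_cdf_isotropic_in_solid_angle(self, mono60, coarse_geometry):
        # isotropic in the cone <=> cos(theta) uniform on [cos(14 deg), 1]
        _, dirs, _ = emit_photon(coarse_geometry, mono60, n=100_000, seed=2)
        cos_t = dirs @ np.array([1.0, 0, 0])
        c0 = np.cos(np.radians(14.0))
        u = (1.0 - cos_t) / (1.0 - c0)
        assert stats.kstest(u, "uniform").pvalue > 0.01


class TestComptonSampling:
    def test_energy_angle_relation_exact(self):
        e, ct = sample_compton(60.0, n=5_000, seed=3)
        a = 60.0 / MEC2
        np.testing.assert_allclose(e, 60.0 / (1.0 + a * (1.0 - ct)), rtol=1e-12)
        assert np.all(e > 0) and np.all(e <= 60.0)

    def test_forward_scatter_preserves_energy(self):
        # the kinematic formula at theta = 0 (and the 511 keV / 90 deg case)
        a = 511.0 / MEC2
        assert 511.0 / (1.0 + a * (1.0 - 1.0)) == pytest.approx(511.0)
        assert 511.0 / (1.0 + a * 1.0) == pytest.approx(255.5, abs=0.01)

    def test_angle_histogram_matches_klein_nishina(self):
        _, ct = sample_compton(60.0, n=100_000, seed=4)
        edges = np.linspace(-1, 1, 41)
        norm = quad(kn_pdf_unnormalized, -1, 1, args=(60.0,))[0]
        expected = np.array([
            quad(kn_pdf_unnormalized, edges[k], edges[k + 1], args=(60.0,))[0] / norm
            for k in range(40)
        ]) * ct.size
        observed, _ = np.histogram(ct, bins=edges)
        chi2 = ((observed - expected) ** 2 / expected).sum()
        assert stats.chi2.sf(chi2, 39) > 0.01

    def test_mean_cosine_matches_quadrature(self):
        _, ct = sample_compton(60.0, n=100_000, seed=5)
        norm = quad(kn_pdf_unnormalized, -1, 1, args=(60.0,))[0]
        mean_exp = quad(lambda c: c * kn_pdf_unnormalized(c, 60.0), -1, 1)[0] / norm
        se = ct.std() / np.sqrt(ct.size)
        assert abs(ct.mean() - mean_exp) < 3 * se


class TestRayleighSampling:
    def test_elastic_no_energy_change(self):
        # the API returns only an angle: coherent scattering leaves E untouched
        ct = sample_rayleigh(60.0, n=10, seed=0)
        assert np.all((-1 <= ct) & (ct <= 1))

    def test_angle_histogram_matches_thomson_shape(self):
        ct = sample_rayleigh(60.0, n=100_000, seed=6)
        edges = np.linspace(-1, 1, 41)
        expected = np.array([
            quad(lambda c: 0.375 * (1 + c * c), edges[k], edges[k + 1])[0]
            for k in range(40)
        ]) * ct.size
        observed, _ = np.histogram(ct, bins=edges)
        chi2 = ((observed - expected) ** 2 / expected).sum()
        assert stats.chi2.sf(chi2, 39) > 0.01


class TestTransport:
    def test_vacuum_phantom_no_scatter(self, mono60, coarse_geometry):
        ph = VoxelPhantom(np.zeros((8, 8, 8), dtype=np.float32), (4, 4, 4),
                          (-16, -16, -16))
        tally = run_projection_mc(ph, coarse_geometry, mono60, 50_000, seed=7)
        assert tally.scatter.pixels.sum() == 0
        assert tally.absorbed == 0
        assert tally.conservation_ok()

    def test_same_seed_bit_identical(self, mono60, water_cylinder, coarse_geometry):
        a = run_projection_mc(water_cylinder, coarse_geometry, mono60, 30_000, seed=9)
        b = run_projection_mc(water_cylinder, coarse_geometry, mono60, 30_000, seed=9)
        np.testing.assert_array_equal(a.primary.pixels, b.primary.pixels)
        np.testing.assert_array_equal(a.scatter.pixels, b.scatter.pixels)
        assert (a.absorbed, a.missed) == (b.absorbed, b.missed)

    def test_photon_conservation_exact(self, spectrum90, water_cylinder,
                                       coarse_geometry):
        tally = run_projection_mc(water_cylinder, coarse_geometry, spectrum90,
                                  200_000, seed=10)
        p, s = tally.tallied
        assert tally.absorbed + tally.missed + p + s == tally.photons_emitted

    def test_slab_beer_lambert_zero_interaction_fraction(self, mono60):
        # narrow 2-degree cone through a 50 mm water slab: the fraction of
        # detected photons with zero interactions must follow exp(-mu L)
        with pytest.warns(UserWarning, match="cone half-angle"):
            geo = CBCTGeometry(detector_pixels=(16, 16), pixel_pitch=4.0,
                               view_angles=np.array([0.0]),
                               cone_half_angle_limit=2.0)
        density = np.ones((25, 100, 100), dtype=np.float32)
        ph = VoxelPhantom(density, (2.0, 2.0, 2.0), (-25.0, -100.0, -100.0))
        n = 300_000
        tally = run_projection_mc(ph, geo, mono60, n, seed=11)
        expected = expected_primary_counts(ph, geo, mono60, 0.0, n, supersample=2)
        mu_mm = mu_linear(get_material("soft_tissue"), 60.0, 1.0) / 10.0
        # the oracle itself is Beer-Lambert: near-axial rays see ~50 mm water
        omega = expected_primary_counts(
            VoxelPhantom(np.zeros((2, 2, 2), dtype=np.float32), (1, 1, 1),
                         (-1, -1, -1)), geo, mono60, 0.0, n)
        assert expected[8, 8] / omega[8, 8] == pytest.approx(
            np.exp(-mu_mm * 50.0), rel=1e-3)
        # the detector covers the whole cone and the slab covers every ray,
        # so the overall zero-interaction detected fraction is Beer-Lambert
        observed_frac = tally.primary.pixels.sum() / n
        p_exp = np.exp(-mu_mm * 50.0)
        sigma = np.sqrt(p_exp * (1 - p_exp) / n)
        assert abs(observed_frac - p_exp) < 4 * sigma

    def test_primary_tally_matches_analytic_oracle(self, spectrum90, water_cylinder,
                                                   coarse_geometry):
        n = 400_000
        tally = run_projection_mc(water_cylinder, coarse_geometry, spectrum90, n,
                                  seed=12)
        expected = expected_primary_counts(water_cylinder, coarse_geometry,
                                           spectrum90, 0.0, n, supersample=4)
        z = (tally.primary.pixels - expected) / np.sqrt(np.maximum(expected, 1.0))
        assert (np.abs(z) > 4).mean() <= 0.01

    def test_seed_independence_poisson_consistent(self, mono60, water_cylinder,
                                                  coarse_geometry):
        a = run_projection_mc(water_cylinder, coarse_geometry, mono60, 200_000, seed=1)
        b = run_projection_mc(water_cylinder, coarse_geometry, mono60, 200_000, seed=2)
        pa, sa = a.tallied
        pb, sb = b.tallied
        assert abs(pa - pb) < 4 * np.sqrt(pa + pb)
        assert abs(sa - sb) < 4 * np.sqrt(sa + sb + 1)

    def test_scatter_image_is_low_frequency(self, spectrum90, water_cylinder):
        geo = CBCTGeometry(detector_pixels=(32, 24), pixel_pitch=7.62,
                           view_angles=np.array([0.0]))
        tally = run_projection_mc(water_cylinder, geo, spectrum90, 20_000_000,
                                  seed=13)
        s = tally.scatter.pixels
        power = np.fft.fftshift(np.abs(np.fft.fft2(s)) ** 2)
        fv = np.fft.fftshift(np.fft.fftfreq(s.shape[0]))
        fu = np.fft.fftshift(np.fft.fftfreq(s.shape[1]))
        r = np.sqrt(fv[:, None] ** 2 + fu[None, :] ** 2)
        power[s.shape[0] // 2, s.shape[1] // 2] = 0.0  # DC excluded
        frac = power[r <= 0.125].sum() / power.sum()
        # dominated by low frequencies already at modest statistics
        assert frac > 0.6
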
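"""Deterministic analytic projector (attenuation-only).

Serves two roles: the noiseless "experimental" primary-signal generator
for synthetic studies, and the independent oracle the Monte Carlo primary
tally is checked against. Pixel values are Beer-Lambert transmitted
intensities integrated over the spectrum; by default the blank (empty
beam) response is flat across the detector — the blank-scan ratio used by
the correction chain cancels first-order geometric falloff — with an
optional solid-angle falloff mode for absolute photon-count expectations.
"""

from __future__ import annotations

import numpy as np

from ._kernels import analytic_primary_kernel, ray_voxel_path
from .geometry import CBCTGeometry, ProjectionImage, view_basis
from .materials import get_material, partial_attenuation
from .phantom import VoxelPhantom
from .spectrum import EnergySpectrum

__all__ = ["siddon_path", "analytic_primary", "blank_scan", "expected_primary_counts"]

_CLASS_NAMES = ("air", "soft_tissue", "bone")


def spectrum_kappa_table(spectrum: EnergySpectrum) -> np.ndarray:
    """Total mass attenuation (cm^2/g) of the three phantom material
    classes at every spectrum bin energy; shape (3, n_bins)."""
    kappa = np.empty((3, spectrum.energy_bins.size))
    for m, name in enumerate(_CLASS_NAMES):
        pe, co, ra = partial_attenuation(get_material(name), spectrum.energy_bins)
        kappa[m] = pe + co + ra
    return kappa


def siddon_path(phantom: VoxelPhantom, p0, p1):
    """Exact voxel traversal of the segment p0 -> p1 (mm, world frame).

    Returns ``(indices, lengths)``: an (n, 3) int array of voxel indices
    and the chord length (mm) of the segment inside each, in traversal
    order. The lengths sum to the segment's intersection with the grid
    bounding box. A zero-length segment raises ValueError.
    """
    p0 = np.asarray(p0, dtype=np.float64)
    p1 = np.asarray(p1, dtype=np.float64)
    shape = np.asarray(phantom.shape, dtype=np.int64)
    cap = int(shape.sum()) + 4
    out_idx = np.empty((cap, 3), dtype=np.int64)
    out_len = np.empty(cap, dtype=np.float64)
    n = ray_voxel_path(
        p0, p1,
        np.asarray(phantom.origin), np.asarray(phantom.voxel_size),
        shape, out_idx, out_len,
    )
    if n < 0:
        raise ValueError("degenerate (zero-length) ray")
    return out_idx[:n].copy(), out_len[:n].copy()


def _project_view(phantom, geometry, spectrum, view_angle, supersample):
    axis, u_hat, v_hat = view_basis(view_angle)
    source = -geometry.d_so * axis
    det_center = geometry.d_od * axis
    out = np.empty((geometry.nv, geometry.nu))
    analytic_primary_kernel(
        source, det_center, u_hat, v_hat,
        geometry.nu, geometry.nv, geometry.pixel_pitch,
        phantom.transport_density, phantom.material_id,
        np.asarray(phantom.origin), np.asarray(phantom.voxel_size),
        spectrum.probabilities, spectrum_kappa_table(spectrum),
        supersample, out,
    )
    return out


def _falloff_map(geometry: CBCTGeometry) -> np.ndarray:
    """Relative solid-angle factor cos^3(theta) per pixel (1 on axis)."""
    u, v = geometry.pixel_centers_uv()
    r2 = u[None, :] ** 2 + v[:, None] ** 2
    cos_t = geometry.d_sd / np.sqrt(geometry.d_sd**2 + r2)
    return cos_t**3


def analytic_primary(
    phantom: VoxelPhantom,
    geometry: CBCTGeometry,
    spectrum: EnergySpectrum,
    view_angle: float,
    scale: float = 1.0,
    supersample: int = 1,
    physical_falloff: bool = False,
) -> ProjectionImage:
    """Noiseless primary projection of the phantom at one view.

    Pixel value = scale * sum_E fluence(E) * exp(-sum mu(E) * length) along
    the source -> pixel-center ray (averaged over ``supersample``^2
    sub-pixel rays when requested). ``physical_falloff`` multiplies in the
    relative cos^3 solid-angle factor; the default is a flat blank response.
    """
    trans = _project_view(phantom, geometry, spectrum, view_angle, supersample)
    pixels = scale * spectrum.total_fluence * trans
    if physical_falloff:
        pixels = pixels * _falloff_map(geometry)
    return ProjectionImage(pixels, view_angle=view_angle, role="primary")


def blank_scan(geometry: CBCTGeometry, spectrum: EnergySpectrum,
               scale: float = 1.0, physical_falloff: bool = False) -> ProjectionImage:
    """Detector response with no object in the beam (flat by default)."""
    pixels = np.full((geometry.nv, geometry.nu), scale * spectrum.total_fluence)
    if physical_falloff:
        pixels = pixels * _falloff_map(geometry)
    return ProjectionImage(pixels, view_angle=0.0, role="blank")


def pixel_solid_angle_fractions(geometry: CBCTGeometry) -> np.ndarray:
    """Fraction of the emission cone's solid angle subtended by each pixel.

    Small-pixel approximation dOmega = A cos^3(theta) / D_SD^2, divided by
    the cone solid angle 2 pi (1 - cos(half angle)).
    """
    omega_cone = 2.0 * np.pi * (1.0 - np.cos(np.radians(geometry.cone_half_angle_limit)))
    a_pix = geometry.pixel_pitch**2
    return _falloff_map(geometry) * a_pix / geometry.d_sd**2 / omega_cone


def expected_primary_counts(
    phantom: VoxelPhantom,
    geometry: CBCTGeometry,
    spectrum: EnergySpectrum,
    view_angle: float,
    n_photons: int,
    supersample: int = 2,
) -> np.ndarray:
    """Expected Monte Carlo primary-tally counts per pixel.

    n_photons times the per-pixel probability that an emitted photon both
    falls in the pixel's solid angle and traverses the object uninteracted.
    This is the oracle for the MC primary consistency check.
    """
    trans = _project_view(phantom, geometry, spectrum, view_angle, supersample)
    return n_photons * pixel_solid_angle_fractions(geometry) * trans
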
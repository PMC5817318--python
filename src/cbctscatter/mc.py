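"""Monte Carlo photon transport with interaction counting.

Analog (unweighted) transport of photons from a disc focal spot through
the voxel phantom to an ideal photon-counting detector. Free paths are
sampled by Woodcock delta-tracking against an energy-dependent majorant;
real interactions are photoelectric absorption, free-electron Compton
scattering (Klein-Nishina, sampled with Kahn's method) and coherent
Rayleigh scattering with the Thomson (1 + cos^2) angular shape. Each
photon's interactions inside the object are counted: photons arriving
with zero interactions tally into the primary image, all others into the
scatter image — the separation the whole correction chain is built on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .geometry import CBCTGeometry, ProjectionImage, view_basis
from .materials import get_material, partial_attenuation
from .phantom import VoxelPhantom
from .spectrum import EnergySpectrum

__all__ = [
    "TallyPair",
    "run_projection_mc",
    "sample_compton",
    "sample_rayleigh",
    "emit_photon",
    "FINE_GRID",
]

# fine energy grid used by the in-kernel attenuation lookups
FINE_GRID = (10.0, 0.25, 361)   # (e0 keV, de keV, n)
DEFAULT_ENERGY_CUTOFF_KEV = 5.0
DEFAULT_FOCAL_DIAMETER_MM = 0.6


@dataclass
class TallyPair:
    """Primary and scatter detector tallies from one MC projection."""

    primary: ProjectionImage
    scatter: ProjectionImage
    photons_emitted: int
    seed: int
    absorbed: int = 0
    missed: int = 0

    @property
    def tallied(self) -> tuple[int, int]:
        return (int(self.primary.pixels.sum()), int(self.scatter.pixels.sum()))

    def conservation_ok(self) -> bool:
        p, s = self.tallied
        return self.absorbed + self.missed + p + s == self.photons_emitted


def _class_tables():
    """Partial mass attenuation lookup tables on the fine energy grid."""
    e0, de, n = FINE_GRID
    energies = e0 + de * np.arange(n)
    mu_pe = np.empty((3, n))
    mu_co = np.empty((3, n))
    mu_ra = np.empty((3, n))
    for m, name in enumerate(("air", "soft_tissue", "bone")):
        pe, co, ra = partial_attenuation(get_material(name), energies)
        mu_pe[m] = pe
        mu_co[m] = co
        mu_ra[m] = ra
    return energies, mu_pe, mu_co, mu_ra


def _majorant(phantom: VoxelPhantom, mu_pe, mu_co, mu_ra) -> np.ndarray:
    """Per-energy majorant linear attenuation (1/mm) over the phantom."""
    density = phantom.transport_density
    matid = phantom.material_id
    total = mu_pe + mu_co + mu_ra
    maj = np.zeros(total.shape[1])
    for m in range(3):
        sel = matid == m
        if np.any(sel):
            maj = np.maximum(maj, 0.1 * float(density[sel].max()) * total[m])
    return maj


def view_seed(base_seed: int, view_index: int) -> int:
    """Independent per-view RNG stream seed (kept below 2**31)."""
    ss = np.random.SeedSequence([int(base_seed), int(view_index)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def run_projection_mc(
    phantom: VoxelPhantom,
    geometry: CBCTGeometry,
    spectrum: EnergySpectrum,
    n_photons: int,
    view_angle: float = 0.0,
    seed: int = 0,
    energy_cutoff_kev: float = DEFAULT_ENERGY_CUTOFF_KEV,
    focal_diameter_mm: float = DEFAULT_FOCAL_DIAMETER_MM,
) -> TallyPair:
    """Simulate one projection; returns separate primary/scatter tallies.

    Reproducible: a fixed (seed, inputs) pair gives bit-identical tallies.
    Photon bookkeeping is exact: emitted = absorbed + missed + tallied.
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    axis, u_hat, v_hat = view_basis(view_angle)
    source = -geometry.d_so * axis
    det_center = geometry.d_od * axis

    e0, de, _ = FINE_GRID
    _, mu_pe, mu_co, mu_ra = _class_tables()
    maj = _majorant(phantom, mu_pe, mu_co, mu_ra)

    probs = spectrum.probabilities
    cdf = np.cumsum(probs)
    cdf[-1] = 1.0

    primary = np.zeros((geometry.nv, geometry.nu))
    scatter = np.zeros((geometry.nv, geometry.nu))
    counters = np.zeros(4, dtype=np.int64)
    _kernels.run_mc_kernel(
        int(seed) % (2**31 - 1), int(n_photons),
        source, axis, u_hat, v_hat,
        focal_diameter_mm / 2.0,
        float(np.cos(np.radians(geometry.cone_half_angle_limit))),
        det_center, geometry.nu, geometry.nv, geometry.pixel_pitch,
        phantom.transport_density, phantom.material_id,
        np.asarray(phantom.origin), np.asarray(phantom.voxel_size),
        cdf, spectrum.energy_bins.astype(np.float64),
        e0, de, mu_pe, mu_co, mu_ra, maj, energy_cutoff_kev,
        primary, scatter, counters,
    )
    return TallyPair(
        primary=ProjectionImage(primary, view_angle=view_angle, role="primary"),
        scatter=ProjectionImage(scatter, view_angle=view_angle, role="scatter"),
        photons_emitted=int(n_photons),
        seed=int(seed),
        absorbed=int(counters[0]),
        missed=int(counters[1]),
    )


def simulate_views(
    phantom: VoxelPhantom,
    geometry: CBCTGeometry,
    spectrum: EnergySpectrum,
    n_photons_per_view: int,
    seed: int = 0,
    **kwargs,
) -> list[TallyPair]:
    """Run the MC projector over every view angle of the geometry."""
    return [
        run_projection_mc(
            phantom, geometry, spectrum, n_photons_per_view,
            view_angle=float(angle), seed=view_seed(seed, k), **kwargs,
        )
        for k, angle in enumerate(geometry.view_angles)
    ]


# --- single-process sampling helpers (also exercised by the tests) --------

def sample_compton(energy_kev: float, n: int = 1, seed: int = 0):
    """Sample (scattered energy keV, cos polar angle) pairs at one energy.

    Klein-Nishina free-electron law via Kahn's rejection method; the
    scattered energy follows E' = E / (1 + (E/m_e c^2)(1 - cos theta)).
    """
    if energy_kev <= 0:
        raise ValueError("energy must be positive")
    out_e = np.empty(n)
    out_ct = np.empty(n)
    _sample_compton_batch(int(seed) % (2**31 - 1), float(energy_kev), out_e, out_ct)
    if n == 1:
        return float(out_e[0]), float(out_ct[0])
    return out_e, out_ct


def sample_rayleigh(energy_kev: float, n: int = 1, seed: int = 0):
    """Sample cos polar angles for coherent scattering (energy unchanged).

    Angular law: Thomson (1 + cos^2 theta) shape, azimuthally uniform.
    """
    if energy_kev <= 0:
        raise ValueError("energy must be positive")
    out = np.empty(n)
    _sample_thomson_batch(int(seed) % (2**31 - 1), out)
    if n == 1:
        return float(out[0])
    return out


def emit_photon(
    geometry: CBCTGeometry,
    spectrum: EnergySpectrum,
    n: int = 1,
    seed: int = 0,
    focal_diameter_mm: float = DEFAULT_FOCAL_DIAMETER_MM,
    view_angle: float = 0.0,
):
    """Sample initial photon states for one view.

    Returns (positions (n,3) mm, directions (n,3) unit, energies (n,) keV):
    positions uniform on the focal disc, directions isotropic within the
    cone half-angle about the beam axis, energies from the spectrum.
    """
    rng = np.random.default_rng(seed)
    axis, u_hat, v_hat = view_basis(view_angle)
    source = -geometry.d_so * axis

    r = focal_diameter_mm / 2.0 * np.sqrt(rng.random(n))
    phi = 2.0 * np.pi * rng.random(n)
    pos = (source[None, :]
           + (r * np.cos(phi))[:, None] * u_hat[None, :]
           + (r * np.sin(phi))[:, None] * v_hat[None, :])

    cos_min = np.cos(np.radians(geometry.cone_half_angle_limit))
    ct = 1.0 - rng.random(n) * (1.0 - cos_min)
    st = np.sqrt(1.0 - ct**2)
    phi = 2.0 * np.pi * rng.random(n)
    dirs = (ct[:, None] * axis[None, :]
            + (st * np.cos(phi))[:, None] * u_hat[None, :]
            + (st * np.sin(phi))[:, None] * v_hat[None, :])

    idx = rng.choice(spectrum.energy_bins.size, size=n, p=spectrum.probabilities)
    energies = spectrum.energy_bins[idx]
    return pos, dirs, energies


import numba as nb  # noqa: E402  (kernel helpers defined after API)


@nb.njit(cache=True)
def _sample_compton_batch(seed, e_kev, out_e, out_ct):
    np.random.seed(seed)
    for i in range(out_e.size):
        e, ct = _kernels._sample_compton(e_kev)
        out_e[i] = e
        out_ct[i] = ct


@nb.njit(cache=True)
def _sample_thomson_batch(seed, out_ct):
    np.random.seed(seed)
    for i in range(out_ct.size):
        out_ct[i] = _kernels._sample_thomson()
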
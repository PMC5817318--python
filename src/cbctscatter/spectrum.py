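"""X-ray energy spectra: representation, sampling, HVL matching.

A spectrum is a binned relative fluence on a uniform keV grid, the way
spectrum calculators export tube output. The half-value layer (HVL)
utilities treat the beam in narrow-beam geometry (pure exponential
attenuation, no buildup): the HVL here is a beam-quality descriptor used
to harden a calculated spectrum to match a measured system, not a
transport result.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .materials import Material, get_material, mass_attenuation

__all__ = [
    "EnergySpectrum",
    "sample_energy",
    "compute_hvl",
    "match_hvl",
    "make_fixture_spectrum",
]

# standard densities (g/cm^3) for filtration / HVL calculations
_FILTER_DENSITY = {"aluminum": 2.699, "soft_tissue": 1.0, "air": 1.205e-3, "bone": 1.92}


class InvalidSpectrumError(ValueError):
    pass


@dataclass(frozen=True)
class EnergySpectrum:
    """Binned relative photon fluence on an ascending uniform keV grid."""

    energy_bins: np.ndarray   # bin centers, keV, strictly increasing, uniform
    fluence: np.ndarray       # relative photon counts per bin, >= 0
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        e = np.asarray(self.energy_bins, dtype=float)
        f = np.asarray(self.fluence, dtype=float)
        object.__setattr__(self, "energy_bins", e)
        object.__setattr__(self, "fluence", f)
        if e.ndim != 1 or e.shape != f.shape:
            raise InvalidSpectrumError("energy and fluence must be matching 1-D arrays")
        if e.size > 1:
            d = np.diff(e)
            if np.any(d <= 0):
                raise InvalidSpectrumError("bin energies must be strictly increasing")
            if not np.allclose(d, d[0], rtol=1e-6):
                raise InvalidSpectrumError("bin width must be uniform")
        if np.any(f < 0):
            raise InvalidSpectrumError("fluence values must be non-negative")
        if not np.any(f > 0):
            raise InvalidSpectrumError("spectrum has no populated bin")

    @property
    def bin_width(self) -> float:
        e = self.energy_bins
        return float(e[1] - e[0]) if e.size > 1 else 1.0

    @property
    def probabilities(self) -> np.ndarray:
        """Per-bin sampling probabilities (normalized fluence)."""
        return self.fluence / self.fluence.sum()

    @property
    def total_fluence(self) -> float:
        return float(self.fluence.sum())

    def mean_energy(self) -> float:
        return float(np.sum(self.probabilities * self.energy_bins))

    def filtered(self, material: Material, thickness_mm: float,
                 density: float | None = None) -> "EnergySpectrum":
        """Spectrum after narrow-beam filtration by `thickness_mm` of material."""
        if thickness_mm < 0:
            raise ValueError("filtration thickness must be non-negative")
        rho = _FILTER_DENSITY.get(material.name, 1.0) if density is None else density
        mu = mass_attenuation(material, self.energy_bins) * rho  # 1/cm
        f = self.fluence * np.exp(-mu * thickness_mm / 10.0)
        return EnergySpectrum(self.energy_bins.copy(), f, name=self.name)

    # --- I/O: two-column text, '#' comments -------------------------------

    def to_text(self) -> str:
        buf = io.StringIO()
        buf.write("# energy_keV fluence\n")
        for e, f in zip(self.energy_bins, self.fluence):
            buf.write(f"{e:.6g} {f:.8g}\n")
        return buf.getvalue()

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())

    @classmethod
    def load(cls, path) -> "EnergySpectrum":
        data = np.loadtxt(path, comments="#", ndmin=2)
        if data.shape[1] < 2:
            raise InvalidSpectrumError("spectrum file needs two columns")
        return cls(data[:, 0], data[:, 1])


def sample_energy(spectrum: EnergySpectrum, n: int, seed: int) -> np.ndarray:
    """Draw `n` photon energies (bin centers) from the spectrum.

    The sampling distribution is the normalized fluence; returned values
    are the centers of the populated bins.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.choice(spectrum.energy_bins.size, size=n, p=spectrum.probabilities)
    return spectrum.energy_bins[idx]


def _transmission(spectrum: EnergySpectrum, mu_per_cm: np.ndarray, t_mm: float) -> float:
    """Fluence-weighted transmitted fraction through thickness t_mm."""
    w = spectrum.probabilities
    return float(np.sum(w * np.exp(-mu_per_cm * t_mm / 10.0)))


def compute_hvl(spectrum: EnergySpectrum, material: Material,
                density: float | None = None) -> float:
    """Half-value layer (mm) of `material` for the spectrum.

    Narrow-beam geometry: the thickness t solving
    sum_E w(E) exp(-mu(E) t) = 1/2, found by bracketing + Brent to a
    relative tolerance of 1e-6.
    """
    rho = _FILTER_DENSITY.get(material.name, 1.0) if density is None else density
    mu = mass_attenuation(material, spectrum.energy_bins) * rho  # 1/cm
    if np.all(mu[spectrum.probabilities > 0] <= 0):
        raise ValueError("material does not attenuate the spectrum")

    def g(t):
        return _transmission(spectrum, mu, t) - 0.5

    hi = 1.0
    for _ in range(200):
        if g(hi) < 0:
            break
        hi *= 2.0
    else:
        raise RuntimeError("HVL bracketing failed to converge")
    return float(brentq(g, 0.0, hi, rtol=1e-9, xtol=1e-9))


def match_hvl(spectrum: EnergySpectrum, target_hvl_mm: float,
              filter_material: Material, density: float | None = None,
              tol_mm: float = 1e-4) -> EnergySpectrum:
    """Harden the spectrum by added filtration until its HVL hits a target.

    Multiplies the fluence bin-wise by exp(-mu(E) d) with d >= 0 chosen so
    the filtered spectrum's HVL equals `target_hvl_mm` within `tol_mm`.
    Raises if the target is below the current HVL (filtration can only
    harden) or cannot be reached (e.g. a monoenergetic beam).
    """
    current = compute_hvl(spectrum, filter_material, density)
    if target_hvl_mm < current - tol_mm:
        raise ValueError(
            f"target HVL {target_hvl_mm} mm below current {current:.6f} mm: "
            "added filtration cannot soften a beam"
        )
    if abs(target_hvl_mm - current) <= tol_mm:
        return spectrum

    def g(d):
        return compute_hvl(spectrum.filtered(filter_material, d, density),
                           filter_material, density) - target_hvl_mm

    hi = 1.0
    g_hi = g(hi)
    for _ in range(60):
        if g_hi >= 0:
            break
        hi *= 2.0
        new = g(hi)
        if abs(new - g_hi) < 1e-12 and new < 0:
            raise ValueError("target HVL unreachable by filtration of this spectrum")
        g_hi = new
    else:
        raise ValueError("target HVL unreachable by filtration of this spectrum")
    d = brentq(g, 0.0, hi, xtol=tol_mm / 10.0)
    return spectrum.filtered(filter_material, float(d), density)


def make_fixture_spectrum(kvp: float = 90.0, al_filtration_mm: float = 10.6,
                          e_min: float = 10.0, bin_width: float = 1.0) -> EnergySpectrum:
    """Synthetic bremsstrahlung-like tube spectrum fixture.

    Kramers-law shape (kVp - E)/E filtered by `al_filtration_mm` of
    aluminum; defaults emulate a heavily filtered 90 kVp dental tube.
    Characteristic lines are not modeled. Normalized to unit peak.
    """
    e = np.arange(e_min, kvp, bin_width)
    f = np.clip(kvp - e, 0.0, None) / e
    raw = EnergySpectrum(e, f, name=f"kramers_{kvp:g}kVp")
    filtered = raw.filtered(get_material("aluminum"), al_filtration_mm)
    f = filtered.fluence / filtered.fluence.max()
    return EnergySpectrum(e, f, name=f"fixture_{kvp:g}kVp_{al_filtration_mm:g}mmAl")
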
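"""Transport materials and their photon attenuation data.

Each material carries per-energy mass attenuation coefficients (cm^2/g)
split into photoelectric, Compton (incoherent) and Rayleigh (coherent)
partials on a 1 keV grid covering 10-100 keV. Interpolation between grid
knots is linear in log-log space, which keeps interpolants positive and is
the standard convention for photon cross sections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "Material",
    "get_material",
    "material_names",
    "mu_linear",
    "mass_attenuation",
    "DENSITY_BANDS",
    "DENSITY_CLAMP",
]

# density bands (g/cm^3) used for material classification: lower-inclusive,
# upper-exclusive; densities above the bone band top are clamped for transport
DENSITY_BANDS = {
    "air": (0.0, 0.3),
    "soft_tissue": (0.3, 1.2),
    "bone": (1.2, float("inf")),
}
DENSITY_CLAMP = 1.95


@dataclass(frozen=True)
class Material:
    """A transport material with tabulated partial mass attenuation data."""

    name: str
    density_band: tuple[float, float]
    energies: np.ndarray = field(repr=False)        # keV, strictly increasing
    mu_pe: np.ndarray = field(repr=False)           # cm^2/g
    mu_compton: np.ndarray = field(repr=False)      # cm^2/g
    mu_rayleigh: np.ndarray = field(repr=False)     # cm^2/g

    def __post_init__(self) -> None:
        for arr in (self.mu_pe, self.mu_compton, self.mu_rayleigh):
            if arr.shape != self.energies.shape:
                raise ValueError("attenuation table column shape mismatch")
            if np.any(arr < 0):
                raise ValueError(f"negative attenuation coefficient in {self.name!r}")
        if self.energies.size and np.any(np.diff(self.energies) <= 0):
            raise ValueError("table energies must be strictly increasing")

    @property
    def mu_total(self) -> np.ndarray:
        """Total mass attenuation coefficient: exact sum of the partials."""
        return self.mu_pe + self.mu_compton + self.mu_rayleigh

    @property
    def is_vacuum(self) -> bool:
        return self.name == "vacuum"

    def energy_range(self) -> tuple[float, float]:
        if self.is_vacuum:
            return (0.0, float("inf"))
        return (float(self.energies[0]), float(self.energies[-1]))


def _loglog_interp(x: np.ndarray, xp: np.ndarray, fp: np.ndarray) -> np.ndarray:
    """Log-log linear interpolation; zero table values fall back to linear."""
    if np.any(fp <= 0):
        return np.interp(x, xp, fp)
    return np.exp(np.interp(np.log(x), np.log(xp), np.log(fp)))


def _load_table(name: str) -> Material:
    ref = resources.files("cbctscatter.data").joinpath(f"attenuation/{name}.txt")
    with resources.as_file(ref) as path:
        data = np.loadtxt(path)
    band = DENSITY_BANDS.get(name, (0.0, float("inf")))
    return Material(
        name=name,
        density_band=band,
        energies=np.ascontiguousarray(data[:, 0]),
        mu_pe=np.ascontiguousarray(data[:, 1]),
        mu_compton=np.ascontiguousarray(data[:, 2]),
        mu_rayleigh=np.ascontiguousarray(data[:, 3]),
    )


_VACUUM = Material(
    name="vacuum",
    density_band=(0.0, 0.0),
    energies=np.array([0.0, np.inf]),
    mu_pe=np.zeros(2),
    mu_compton=np.zeros(2),
    mu_rayleigh=np.zeros(2),
)

_CACHE: dict[str, Material] = {}


def material_names() -> tuple[str, ...]:
    return ("air", "soft_tissue", "bone", "aluminum", "vacuum")


def get_material(name: str) -> Material:
    """Return a packaged material by name (cached)."""
    if name == "vacuum":
        return _VACUUM
    if name not in _CACHE:
        if name not in ("air", "soft_tissue", "bone", "aluminum"):
            raise KeyError(f"unknown material {name!r}")
        _CACHE[name] = _load_table(name)
    return _CACHE[name]


def mass_attenuation(material: Material, energy_kev) -> np.ndarray:
    """Total mass attenuation coefficient (cm^2/g) at the given energies."""
    if material.is_vacuum:
        return np.zeros_like(np.asarray(energy_kev, dtype=float))
    e = np.asarray(energy_kev, dtype=float)
    lo, hi = material.energy_range()
    if np.any(e < lo) or np.any(e > hi):
        raise ValueError(
            f"energy outside table range [{lo}, {hi}] keV for {material.name!r}"
        )
    return _loglog_interp(e, material.energies, material.mu_total)


def partial_attenuation(material: Material, energy_kev) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Photoelectric, Compton, Rayleigh mass coefficients at given energies."""
    e = np.asarray(energy_kev, dtype=float)
    if material.is_vacuum:
        z = np.zeros_like(e)
        return z, z.copy(), z.copy()
    lo, hi = material.energy_range()
    if np.any(e < lo) or np.any(e > hi):
        raise ValueError(
            f"energy outside table range [{lo}, {hi}] keV for {material.name!r}"
        )
    return (
        _loglog_interp(e, material.energies, material.mu_pe),
        _loglog_interp(e, material.energies, material.mu_compton),
        _loglog_interp(e, material.energies, material.mu_rayleigh),
    )


def mu_linear(material: Material, energy_kev: float, density: float) -> float:
    """Linear attenuation coefficient (1/cm) at one energy and density.

    Vacuum returns 0 at any energy; otherwise mu = density times the
    log-log-interpolated total mass coefficient.
    """
    if material.is_vacuum:
        return 0.0
    if density < 0:
        raise ValueError("density must be non-negative")
    return float(density * mass_attenuation(material, energy_kev))
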
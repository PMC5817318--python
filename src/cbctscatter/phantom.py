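"""Voxel phantoms: density grids, material classification, synthetic objects.

Conventions (used everywhere in the package): voxel indices are 0-based in
(x, y, z) order; world positions refer to voxel centers; the isocenter (the
scanner rotation axis at mid-plane) is at world coordinate (0, 0, 0).
Material classification follows fixed density bands — air [0, 0.3),
soft tissue [0.3, 1.2), bone [1.2, inf) g/cm^3 — with densities above
1.95 g/cm^3 clamped to 1.95 for transport only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .materials import DENSITY_CLAMP

__all__ = [
    "VoxelPhantom",
    "CalibrationCurve",
    "ct_to_density",
    "classify_material",
    "make_synthetic_head",
    "make_cylinder",
    "MATERIAL_INDEX",
]

# integer labels used in material_id grids (and by the transport kernels)
MATERIAL_INDEX = {"air": 0, "soft_tissue": 1, "bone": 2}
MATERIAL_NAMES = ("air", "soft_tissue", "bone")


def classify_material(density) -> np.ndarray | str:
    """Material label for a density (g/cm^3): air / soft_tissue / bone.

    Bands are lower-inclusive, upper-exclusive; scalar in, scalar label out;
    array in, array of labels out.
    """
    d = np.asarray(density, dtype=float)
    if np.any(d < 0):
        raise ValueError("density must be non-negative")
    idx = classify_material_index(d)
    labels = np.asarray(MATERIAL_NAMES, dtype=object)[idx]
    if np.isscalar(density) or np.ndim(density) == 0:
        return str(labels)
    return labels


def classify_material_index(density) -> np.ndarray:
    """Integer material labels (0=air, 1=soft_tissue, 2=bone)."""
    d = np.asarray(density, dtype=float)
    idx = np.zeros(d.shape, dtype=np.uint8)
    idx[d >= 0.3] = 1
    idx[d >= 1.2] = 2
    return idx


@dataclass
class VoxelPhantom:
    """A 3-D density grid with derived material labels.

    density has shape (nx, ny, nz), g/cm^3; voxel_size is mm per axis;
    origin is the mm offset of the corner of voxel (0,0,0) (its low corner,
    not center) from the isocenter.
    """

    density: np.ndarray
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.density = np.ascontiguousarray(self.density, dtype=np.float32)
        if self.density.ndim != 3:
            raise ValueError("density grid must be 3-D")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative everywhere")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        self.origin = tuple(float(v) for v in self.origin)
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.density.shape

    @property
    def material_id(self) -> np.ndarray:
        """Per-voxel material labels derived from the density bands."""
        return classify_material_index(self.density)

    @property
    def transport_density(self) -> np.ndarray:
        """Density grid with the top-band clamp applied (transport only)."""
        return np.minimum(self.density, np.float32(DENSITY_CLAMP))

    def extent_mm(self) -> np.ndarray:
        """Physical size (mm) along each axis."""
        return np.asarray(self.shape) * np.asarray(self.voxel_size)

    def max_radial_extent(self) -> float:
        """Largest distance (mm) from the isocenter to a grid corner in-plane."""
        x0, y0 = self.origin[0], self.origin[1]
        x1 = x0 + self.shape[0] * self.voxel_size[0]
        y1 = y0 + self.shape[1] * self.voxel_size[1]
        corners = [(x0, y0), (x0, y1), (x1, y0), (x1, y1)]
        return max(float(np.hypot(x, y)) for x, y in corners)

    @classmethod
    def centered(cls, density: np.ndarray, voxel_size) -> "VoxelPhantom":
        """Phantom with its grid center placed at the isocenter."""
        vs = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
        origin = -np.asarray(density.shape) * vs / 2.0
        return cls(density, tuple(vs), tuple(origin))

    # --- raw + JSON sidecar I/O ------------------------------------------

    def save(self, path) -> None:
        """Write raw little-endian float32 density + JSON sidecar."""
        path = Path(path)
        self.density.astype("<f4").tofile(path)
        sidecar = {
            "shape": list(self.shape),
            "voxel_size_mm": list(self.voxel_size),
            "origin_mm": list(self.origin),
            "dtype": "float32",
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path) -> "VoxelPhantom":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        shape = tuple(sidecar["shape"])
        data = np.fromfile(path, dtype="<f4")
        if data.size != int(np.prod(shape)):
            raise ValueError(
                f"phantom file size mismatch: expected {int(np.prod(shape))} voxels, "
                f"got {data.size}"
            )
        return cls(data.reshape(shape), sidecar["voxel_size_mm"], sidecar["origin_mm"])


@dataclass(frozen=True)
class CalibrationCurve:
    """Piecewise-linear CT-number to density calibration."""

    ct_numbers: np.ndarray
    densities: np.ndarray

    def __post_init__(self) -> None:
        ct = np.asarray(self.ct_numbers, dtype=float)
        rho = np.asarray(self.densities, dtype=float)
        object.__setattr__(self, "ct_numbers", ct)
        object.__setattr__(self, "densities", rho)
        if ct.size < 2 or ct.shape != rho.shape:
            raise ValueError("calibration curve needs >= 2 (CT, density) pairs")
        if np.any(np.diff(ct) <= 0):
            raise ValueError("CT numbers must be strictly ascending")
        if np.any(rho < 0) or np.any(np.diff(rho) < 0):
            raise ValueError("densities must be non-negative and non-decreasing")

    @classmethod
    def default(cls) -> "CalibrationCurve":
        """Two-point air/water anchored curve: (-1000, 0) and (0, 1)."""
        return cls(np.array([-1000.0, 0.0]), np.array([0.0, 1.0]))

    @classmethod
    def load(cls, path) -> "CalibrationCurve":
        data = np.loadtxt(path, comments="#", ndmin=2)
        return cls(data[:, 0], data[:, 1])


def ct_to_density(ct_volume: np.ndarray, curve: CalibrationCurve) -> np.ndarray:
    """Convert a CT-number grid to density by piecewise-linear interpolation.

    Values outside the calibration range clamp to the end-point densities.
    """
    return np.interp(np.asarray(ct_volume, dtype=float),
                     curve.ct_numbers, curve.densities)


def load_dicom_volume(directory) -> np.ndarray:
    """Optional adapter: read a DICOM slice directory into a CT-number grid.

    Returns an (nx, ny, nz) array ordered by slice position; feed it to
    ``ct_to_density`` with a calibration curve to build a phantom. Requires
    pydicom; the core pipeline never depends on this.
    """
    import pydicom

    paths = sorted(Path(directory).glob("*.dcm"))
    if not paths:
        raise FileNotFoundError(f"no DICOM files in {directory}")
    slices = [pydicom.dcmread(p) for p in paths]
    slices.sort(key=lambda s: float(getattr(s, "SliceLocation", 0.0)))
    vol = np.stack([
        s.pixel_array * float(getattr(s, "RescaleSlope", 1.0))
        + float(getattr(s, "RescaleIntercept", 0.0))
        for s in slices
    ], axis=-1)
    return np.transpose(vol, (1, 0, 2))


def _ellipsoid_mask(xs, ys, zs, center, semi):
    x = (xs[:, None, None] - center[0]) / semi[0]
    y = (ys[None, :, None] - center[1]) / semi[1]
    z = (zs[None, None, :] - center[2]) / semi[2]
    return x * x + y * y + z * z <= 1.0


def make_synthetic_head(
    head_size_mm: tuple[float, float, float] = (160.0, 200.0, 180.0),
    voxel_size_mm: float = 2.0,
    tissue_density: float = 1.0,
    shell_density: float = 1.6,
    shell_thickness_mm: float = 6.0,
    tooth_density: float = 1.9,
    n_teeth: int = 8,
    n_cavities: int = 2,
    asymmetry: float = 0.0,
    margin_mm: float = 10.0,
    seed: int = 0,
) -> VoxelPhantom:
    """Generate a head-like digital phantom.

    The phantom emulates the anthropomorphic head used on real scanners:
    an ellipsoidal soft-tissue body (default 160 x 200 x 180 mm at
    1.0 g/cm^3), a cranial bone shell (1.6 g/cm^3, ~6 mm thick), internal
    air cavities (sinus/airway-like), and tooth-like high-density bone
    inserts (1.9 g/cm^3) arranged on an arch near the occlusal plane, which
    sits at the axial mid-plane. Deterministic for a fixed seed; with
    ``asymmetry=0`` the phantom is mirror-symmetric about the mid-sagittal
    (x = 0) plane up to the voxel grid.
    """
    rng = np.random.default_rng(seed)
    a, b, c = (s / 2.0 for s in head_size_mm)

    grid_mm = np.asarray(head_size_mm) + 2.0 * margin_mm
    shape = tuple(int(np.ceil(g / voxel_size_mm)) for g in grid_mm)
    vs = (voxel_size_mm,) * 3
    origin = tuple(-s * voxel_size_mm / 2.0 for s in shape)

    xs = origin[0] + (np.arange(shape[0]) + 0.5) * voxel_size_mm
    ys = origin[1] + (np.arange(shape[1]) + 0.5) * voxel_size_mm
    zs = origin[2] + (np.arange(shape[2]) + 0.5) * voxel_size_mm

    density = np.zeros(shape, dtype=np.float32)

    outer = _ellipsoid_mask(xs, ys, zs, (0.0, 0.0, 0.0), (a, b, c))
    density[outer] = tissue_density

    if shell_thickness_mm > 0:
        # bone shell over the cranial (upper) half only, like a skull cap
        inner = _ellipsoid_mask(
            xs, ys, zs, (0.0, 0.0, 0.0),
            (a - shell_thickness_mm, b - shell_thickness_mm, c - shell_thickness_mm),
        )
        shell = outer & ~inner
        upper = np.zeros(shape, dtype=bool)
        upper[:, :, zs > -0.1 * c] = True
        density[shell & upper] = shell_density

    # air cavities: sinus-like ellipsoids placed mirror-symmetrically
    for k in range(n_cavities):
        jitter = asymmetry * rng.uniform(-5.0, 5.0, size=3)
        cy = -0.35 * b + 0.25 * b * (k % 2)
        cz = 0.1 * c + 0.15 * c * (k // 2)
        semi = (0.12 * a, 0.10 * b, 0.10 * c)
        for sign in (+1.0, -1.0):
            center = (sign * 0.3 * a + jitter[0] * sign, cy + jitter[1], cz + jitter[2])
            density[_ellipsoid_mask(xs, ys, zs, center, semi)] = 0.0

    # tooth-like inserts on a dental arch at the occlusal plane (z ~ 0)
    if n_teeth > 0:
        arch_r = 0.45 * min(a, b)
        angles = np.linspace(-70.0, 70.0, n_teeth) * np.pi / 180.0
        tooth_semi = (4.0, 4.0, 6.0)
        for ang in angles:
            cx = arch_r * np.sin(ang)
            cy = -b + arch_r * (1.0 + np.cos(ang)) * 0.55
            center = (cx, cy, 0.0)
            density[_ellipsoid_mask(xs, ys, zs, center, tooth_semi)] = tooth_density

    return VoxelPhantom(density, vs, origin)


def make_cylinder(
    radius_mm: float,
    height_mm: float,
    density: float = 1.0,
    voxel_size_mm: float = 2.0,
    margin_mm: float = 8.0,
) -> VoxelPhantom:
    """Axis-aligned uniform cylinder centered at the isocenter (axis = z)."""
    if radius_mm < 0:
        raise ValueError("radius must be non-negative")
    if height_mm <= 0:
        raise ValueError("height must be positive")
    side = 2.0 * (radius_mm + margin_mm)
    nxy = int(np.ceil(side / voxel_size_mm))
    nz = int(np.ceil((height_mm + 2.0 * margin_mm) / voxel_size_mm))
    shape = (nxy, nxy, nz)
    origin = tuple(-s * voxel_size_mm / 2.0 for s in shape)
    xs = origin[0] + (np.arange(nxy) + 0.5) * voxel_size_mm
    zs = origin[2] + (np.arange(nz) + 0.5) * voxel_size_mm

    r2 = xs[:, None] ** 2 + xs[None, :] ** 2
    in_disc = r2 <= radius_mm**2
    in_z = np.abs(zs) <= height_mm / 2.0
    grid = np.zeros(shape, dtype=np.float32)
    grid[in_disc[:, :, None] & in_z[None, None, :]] = density
    return VoxelPhantom(grid, (voxel_size_mm,) * 3, origin)
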
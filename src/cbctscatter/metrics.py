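"""Image-quality metrics: ROI means, contrast, cupping, percent change.

Cupping is quantified on a 1-D profile through a homogeneous region as
100 * (edge - center) / edge using band means — by default the outer 10%
and the central 10% of the profile span. Percent changes are reported to
two decimals with round-half-up, matching how such tables are printed.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .fdk import ReconVolume

__all__ = ["ROISpec", "roi_mean", "contrast", "cupping_percent",
           "percent_change", "extract_profile", "cylinder_cupping"]


@dataclass(frozen=True)
class ROISpec:
    """A measurement region on one axial slice of a volume.

    center is (ix, iy) in voxels; circular ROIs use radius (voxels),
    rectangular ones half_size=(hx, hy).
    """

    slice_index: int
    center: tuple[float, float]
    shape: str = "circle"            # 'circle' | 'rect'
    radius: float = 3.0
    half_size: tuple[float, float] = (3.0, 3.0)
    label: str = ""

    def mask(self, vol_shape: tuple[int, int, int]) -> np.ndarray:
        nx, ny, nz = vol_shape
        if not 0 <= self.slice_index < nz:
            raise IndexError("ROI slice outside volume")
        ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        cx, cy = self.center
        if self.shape == "circle":
            m = (ix - cx) ** 2 + (iy - cy) ** 2 <= self.radius**2
            lo_ok = cx - self.radius >= -0.5 and cy - self.radius >= -0.5
            hi_ok = cx + self.radius <= nx - 0.5 and cy + self.radius <= ny - 0.5
        elif self.shape == "rect":
            hx, hy = self.half_size
            m = (np.abs(ix - cx) <= hx) & (np.abs(iy - cy) <= hy)
            lo_ok = cx - hx >= -0.5 and cy - hy >= -0.5
            hi_ok = cx + hx <= nx - 0.5 and cy + hy <= ny - 0.5
        else:
            raise ValueError(f"unknown ROI shape {self.shape!r}")
        if not (lo_ok and hi_ok):
            raise IndexError("ROI extends outside the volume")
        if m.sum() < 4:
            raise ValueError("ROI smaller than 4 voxels")
        return m


def _voxels(volume) -> np.ndarray:
    return volume.voxels if isinstance(volume, ReconVolume) else np.asarray(volume)


def roi_mean(volume, roi: ROISpec) -> float:
    """Arithmetic mean of the volume over the ROI."""
    v = _voxels(volume)
    m = roi.mask(v.shape)
    return float(v[:, :, roi.slice_index][m].mean())


def contrast(volume, roi_a: ROISpec, roi_b: ROISpec) -> float:
    """Absolute difference of the two ROI means."""
    return abs(roi_mean(volume, roi_a) - roi_mean(volume, roi_b))


def cupping_percent(profile: np.ndarray, edge_frac: float = 0.1,
                    center_frac: float = 0.1) -> float:
    """Cupping magnitude (%) of a profile through a homogeneous region.

    100 * (mean(edge bands) - mean(center band)) / mean(edge bands), with
    the edge bands the outer `edge_frac` of the profile at each end and
    the center band the central `center_frac`. Positive values mean the
    classic scatter cupping (depressed center).
    """
    p = np.asarray(profile, dtype=float)
    n = p.size
    if n < 10:
        raise ValueError("profile too short for band averaging")
    if edge_frac + center_frac >= 1.0:
        raise ValueError("bands overlap")
    ne = max(1, int(round(edge_frac * n)))
    nc = max(1, int(round(center_frac * n)))
    lo = (n - nc) // 2
    edge_mean = float(np.concatenate([p[:ne], p[-ne:]]).mean())
    center_mean = float(p[lo:lo + nc].mean())
    if edge_mean == 0:
        raise ZeroDivisionError("edge band mean is zero; cupping undefined")
    return 100.0 * (edge_mean - center_mean) / edge_mean


def percent_change(before: float, after: float) -> float:
    """Absolute percentage change 100 * |after - before| / |before|,
    rounded half-up to 2 decimals."""
    if before == 0:
        raise ZeroDivisionError("percent change undefined for before = 0")
    value = 100.0 * abs(after - before) / abs(before)
    return float(Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def extract_profile(volume, slice_index: int, axis: str = "x",
                    line_index: int | None = None) -> np.ndarray:
    """1-D profile through an axial slice, along x (default) or y."""
    v = _voxels(volume)
    sl = v[:, :, slice_index]
    if line_index is None:
        line_index = sl.shape[1] // 2 if axis == "x" else sl.shape[0] // 2
    return sl[:, line_index].copy() if axis == "x" else sl[line_index, :].copy()


def cylinder_cupping(volume, radius_mm: float, span_frac: float = 0.8) -> float:
    """Cupping (%) of a z-axis cylinder reconstruction.

    Takes the central-slice profile along x through the cylinder axis,
    restricts it to |x| <= span_frac * radius (excluding the partial-volume
    rim), and applies the band formula.
    """
    vol = volume if isinstance(volume, ReconVolume) else None
    v = _voxels(volume)
    nz = v.shape[2]
    profile = extract_profile(volume, nz // 2, axis="x")
    voxel = vol.voxel_size if vol is not None else 1.0
    nx = v.shape[0]
    x = (np.arange(nx) - (nx - 1) / 2.0) * voxel
    sel = np.abs(x) <= span_frac * radius_mm
    return cupping_percent(profile[sel])
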
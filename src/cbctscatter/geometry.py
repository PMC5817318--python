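"""Circular cone-beam scan geometry.

Frame convention (fixed once, used by every module): right-handed world
coordinates with the rotation axis along +z and the isocenter at the
origin. At view angle 0 the source sits on the -x axis; angles increase
counter-clockwise viewed from +z. The flat detector is perpendicular to
the source-isocenter ray, centered on it, at distance D_OD beyond the
isocenter. Detector pixel indices: i = horizontal (u), j = vertical (v),
0-based, origin at the lower-left pixel as seen from the source; stored
arrays have shape (nv, nu), i.e. v-major.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["CBCTGeometry", "ProjectionImage", "source_and_detector_pose"]


@dataclass(frozen=True, eq=False)
class CBCTGeometry:
    """Cone-beam scanner layout; defaults match a dental CBCT system."""

    d_so: float = 482.0                    # source-isocenter distance, mm
    d_od: float = 226.0                    # isocenter-detector distance, mm
    detector_pixels: tuple[int, int] = (480, 384)   # (nu, nv)
    pixel_pitch: float = 0.508             # mm
    view_angles: np.ndarray = field(default=None)   # degrees
    cone_half_angle_limit: float = 14.0    # degrees

    def __post_init__(self) -> None:
        if self.view_angles is None:
            object.__setattr__(self, "view_angles", np.arange(0.0, 360.0))
        else:
            angles = np.asarray(self.view_angles, dtype=float)
            object.__setattr__(self, "view_angles", angles)
        if self.d_so <= 0 or self.d_od < 0:
            raise ValueError("require d_so > 0 and d_od >= 0")
        if np.any(self.view_angles < 0) or np.any(self.view_angles >= 360):
            raise ValueError("view angles must lie in [0, 360)")
        if self.corner_half_angle_deg() > self.cone_half_angle_limit:
            warnings.warn(
                "detector corners subtend more than the cone half-angle limit; "
                "the beam will not cover the full detector",
                stacklevel=2,
            )

    @property
    def d_sd(self) -> float:
        """Source-detector distance, mm."""
        return self.d_so + self.d_od

    @property
    def nu(self) -> int:
        return self.detector_pixels[0]

    @property
    def nv(self) -> int:
        return self.detector_pixels[1]

    def detector_size_mm(self) -> tuple[float, float]:
        return (self.nu * self.pixel_pitch, self.nv * self.pixel_pitch)

    def corner_half_angle_deg(self) -> float:
        """Half-angle subtended at the source by a detector corner."""
        half_u = self.nu * self.pixel_pitch / 2.0
        half_v = self.nv * self.pixel_pitch / 2.0
        return float(np.degrees(np.arctan2(np.hypot(half_u, half_v), self.d_sd)))

    def pixel_centers_uv(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (u, v) detector coordinates (mm) of pixel centers."""
        u = (np.arange(self.nu) - (self.nu - 1) / 2.0) * self.pixel_pitch
        v = (np.arange(self.nv) - (self.nv - 1) / 2.0) * self.pixel_pitch
        return u, v

    def with_views(self, angles) -> "CBCTGeometry":
        return CBCTGeometry(
            self.d_so, self.d_od, self.detector_pixels, self.pixel_pitch,
            np.asarray(angles, dtype=float), self.cone_half_angle_limit,
        )


def view_basis(view_angle_deg: float):
    """Unit vectors for one view: beam axis a (source->isocenter), detector
    horizontal u and vertical v axes."""
    beta = np.radians(view_angle_deg)
    axis = np.array([np.cos(beta), np.sin(beta), 0.0])
    u_hat = np.array([-np.sin(beta), np.cos(beta), 0.0])
    v_hat = np.array([0.0, 0.0, 1.0])
    return axis, u_hat, v_hat


def source_and_detector_pose(geometry: CBCTGeometry, view_angle_deg: float):
    """Source position (mm) and detector pixel-center positions for a view.

    Returns ``(source, centers)`` where ``centers`` has shape (nv, nu, 3).
    """
    if not np.isfinite(view_angle_deg):
        raise ValueError("view angle must be finite")
    axis, u_hat, v_hat = view_basis(view_angle_deg)
    source = -geometry.d_so * axis
    det_center = geometry.d_od * axis
    u, v = geometry.pixel_centers_uv()
    centers = (
        det_center[None, None, :]
        + u[None, :, None] * u_hat[None, None, :]
        + v[:, None, None] * v_hat[None, None, :]
    )
    return source, centers


@dataclass
class ProjectionImage:
    """One detector image with its view angle and role tag.

    pixels has shape (nv, nu); role is one of {'measured', 'blank',
    'primary', 'scatter', 'corrected'}.
    """

    pixels: np.ndarray
    view_angle: float = 0.0
    role: str = "measured"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("projection image must be 2-D")
        if np.any(self.pixels < 0):
            raise ValueError("projection intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape
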
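"""Projection-stack file format: raw binary + JSON sidecar.

A stack of n_views detector images is stored as one raw little-endian
binary file (view-major, then v-major, then u) in uint16 or float32, with
a JSON sidecar carrying shape, pitch, angles, role and provenance. A
480 x 384 uint16 view occupies exactly 368,640 bytes. uint16 writes clip
at 65535 with a logged warning; float32 is the lossless internal default.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .geometry import ProjectionImage

__all__ = ["ProjectionStackHeader", "write_stack", "read_stack"]

log = logging.getLogger("cbctscatter")

_DTYPES = {"uint16": np.dtype("<u2"), "float32": np.dtype("<f4")}


class StackFormatError(ValueError):
    pass


@dataclass
class ProjectionStackHeader:
    n_views: int
    detector_shape: tuple[int, int]          # (nu, nv)
    pixel_pitch_mm: float
    dtype: str = "float32"                   # 'uint16' | 'float32'
    angles_deg: list[float] = field(default_factory=list)
    role: str = "measured"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dtype not in _DTYPES:
            raise StackFormatError(f"unknown dtype {self.dtype!r}")
        self.detector_shape = tuple(int(v) for v in self.detector_shape)
        if len(self.angles_deg) != self.n_views:
            raise StackFormatError(
                f"angle list length {len(self.angles_deg)} != n_views {self.n_views}"
            )
        if len(set(self.angles_deg)) != len(self.angles_deg):
            raise StackFormatError("view angles must be unique")

    @property
    def nu(self) -> int:
        return self.detector_shape[0]

    @property
    def nv(self) -> int:
        return self.detector_shape[1]

    def expected_bytes(self) -> int:
        return self.n_views * self.nu * self.nv * _DTYPES[self.dtype].itemsize


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack, header: ProjectionStackHeader, path) -> None:
    """Write a (n_views, nv, nu) array (or ProjectionImage list) + sidecar."""
    if isinstance(stack, (list, tuple)):
        data = np.stack([im.pixels if isinstance(im, ProjectionImage) else im
                         for im in stack])
    else:
        data = np.asarray(stack)
    if data.shape != (header.n_views, header.nv, header.nu):
        raise StackFormatError(
            f"stack shape {data.shape} inconsistent with header "
            f"(n_views={header.n_views}, nv={header.nv}, nu={header.nu})"
        )
    dt = _DTYPES[header.dtype]
    if header.dtype == "uint16":
        if np.any(data > 65535) or np.any(data < 0):
            log.warning("uint16 stack write: values clipped to [0, 65535]")
        data = np.clip(np.rint(data), 0, 65535)
    path = Path(path)
    data.astype(dt).tofile(path)
    _sidecar_path(path).write_text(json.dumps(asdict(header), indent=1))


def read_stack(path) -> tuple[np.ndarray, ProjectionStackHeader]:
    """Read and validate a stack; returns (array (n_views, nv, nu), header)."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise StackFormatError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    header = ProjectionStackHeader(
        n_views=meta["n_views"],
        detector_shape=tuple(meta["detector_shape"]),
        pixel_pitch_mm=meta["pixel_pitch_mm"],
        dtype=meta.get("dtype", "float32"),
        angles_deg=list(meta.get("angles_deg", [])),
        role=meta.get("role", "measured"),
        provenance=meta.get("provenance", {}),
    )
    actual = path.stat().st_size
    expected = header.expected_bytes()
    if actual != expected:
        raise StackFormatError(
            f"raw file size mismatch: expected {expected} bytes, got {actual}"
        )
    data = np.fromfile(path, dtype=_DTYPES[header.dtype])
    data = data.reshape(header.n_views, header.nv, header.nu).astype(np.float64)
    return data, header
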
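"""In-memory CT volume container.

Conventions used throughout the package:

* arrays are indexed ``(z, y, x)`` with z the slice (cranio-caudal) axis;
* ``spacing`` and ``origin`` are stored in the same ``(z, y, x)`` order, in
  millimetres;
* world coordinates are ``(z, y, x)`` positions in mm, computed as
  ``origin + index * spacing`` (voxel centres).

File readers/writers (:mod:`calciscan.io`) translate to and from the
``(x, y, z)`` order used by ITK/NIfTI headers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CTVolume"]


@dataclass
class CTVolume:
    """A 3D CT volume in Hounsfield units with anisotropic voxel spacing.

    Parameters
    ----------
    hu
        3D array of Hounsfield units, shape ``(nz, ny, nx)``.
    spacing
        Voxel spacing ``(z, y, x)`` in mm; strictly positive.
    origin
        World position of voxel ``(0, 0, 0)`` in mm, ``(z, y, x)`` order.
    scan_id
        Identifier carried through score tables.
    meta
        Free-form metadata (e.g. reconstructed ``slice_thickness_mm``, which
        for overlapping reconstructions differs from the z spacing).
    """

    hu: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    scan_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu)
        if self.hu.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.hu.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        if not np.all(np.isfinite(self.hu)):
            raise ValueError("HU values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.hu.shape

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    @property
    def extent_mm(self) -> np.ndarray:
        """Physical size of the field of view per axis (z, y, x), mm."""
        return np.asarray(self.shape) * np.asarray(self.spacing)

    def index_to_world(self, idx) -> np.ndarray:
        """Map (fractional) voxel indices to world mm, ``(..., 3)`` in (z,y,x)."""
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def world_to_index(self, point_mm) -> np.ndarray:
        """Map world mm to fractional voxel indices."""
        point_mm = np.asarray(point_mm, dtype=float)
        return (point_mm - np.asarray(self.origin)) / np.asarray(self.spacing)
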
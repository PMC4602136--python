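"""In-memory containers for 3-D scalar volumes and deformation fields.

A :class:`VolumeMap` is the common currency of the pipeline: volume-change
maps, brain masks, lesion masks, eigenimages and lesion-density maps are all
3-D scalar grids with an isotropic voxel size and an origin offset in mm.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["VolumeMap", "DeformationField", "GeometryError"]


class GeometryError(ValueError):
    """Raised when two volumes that must share a grid do not."""


@dataclass
class VolumeMap:
    """A 3-D scalar grid with geometry metadata.

    Parameters
    ----------
    data:
        3-D array of scalar values (float or integer).
    voxel_size_mm:
        Isotropic voxel edge length in mm; must be positive.
    origin_mm:
        World-space coordinate of voxel (0, 0, 0), in mm.
    name:
        Optional descriptive label carried through reports.
    """

    data: np.ndarray
    voxel_size_mm: float = 2.0
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError("all three dimensions must be >= 1")
        if not self.voxel_size_mm > 0:
            raise ValueError("voxel size must be positive")
        self.origin_mm = tuple(float(c) for c in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_cc(self) -> float:
        """Volume of one voxel in cm^3 (2 mm voxel -> 0.008 cc)."""
        return (self.voxel_size_mm / 10.0) ** 3

    def same_geometry(self, other: "VolumeMap | DeformationField") -> bool:
        return (
            self.shape == other.shape[:3]
            and np.isclose(self.voxel_size_mm, other.voxel_size_mm)
            and np.allclose(self.origin_mm, other.origin_mm)
        )

    def check_geometry(self, other: "VolumeMap | DeformationField") -> None:
        if not self.same_geometry(other):
            raise GeometryError(
                f"geometry mismatch: {self.shape}@{self.voxel_size_mm}mm vs "
                f"{other.shape}@{other.voxel_size_mm}mm"
            )

    def with_data(self, data: np.ndarray, name: str | None = None) -> "VolumeMap":
        """New map sharing this geometry."""
        return replace(self, data=np.asarray(data), name=self.name if name is None else name)

    def voxel_to_mm(self, idx: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of integer voxel indices."""
        return np.asarray(idx, dtype=float) * self.voxel_size_mm + np.asarray(self.origin_mm)

    def is_binary(self) -> bool:
        return bool(np.isin(self.data, (0, 1)).all())


@dataclass
class DeformationField:
    """Per-voxel 3-vector displacement field, in mm.

    ``data`` has shape (nx, ny, nz, 3); component ``i`` is the displacement
    along grid axis ``i``.
    """

    data: np.ndarray
    voxel_size_mm: float = 2.0
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4 or self.data.shape[-1] != 3:
            raise ValueError("deformation field must have shape (nx, ny, nz, 3)")
        if not self.voxel_size_mm > 0:
            raise ValueError("voxel size must be positive")
        if not np.isfinite(self.data).all():
            raise ValueError("deformation field must be finite everywhere")
        self.origin_mm = tuple(float(c) for c in self.origin_mm)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape
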
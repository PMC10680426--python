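"""Voxel lattice containers: binary structure masks and absolute dose grids.

Conventions
-----------
Arrays are indexed ``(ix, iy, iz)`` with the z axis running inferior →
superior ("slices" are fixed-z planes, as in axial CT).  ``origin`` is the
centre of voxel ``(0, 0, 0)`` in cm, so the centre of voxel ``(i, j, k)``
sits at ``origin + (i*dx, j*dy, k*dz)``.  All lengths are cm, volumes cc,
doses Gy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError

__all__ = ["StructureMask", "DoseGrid"]


def _validate_lattice(origin, spacing, shape) -> tuple[np.ndarray, np.ndarray]:
    origin = np.asarray(origin, dtype=float)
    spacing = np.asarray(spacing, dtype=float)
    if origin.shape != (3,) or spacing.shape != (3,):
        raise GeometryError("origin and spacing must be length-3 (x, y, z)")
    if not np.all(spacing > 0):
        raise GeometryError(f"spacing must be strictly positive, got {spacing}")
    if len(shape) != 3 or any(s < 1 for s in shape):
        raise GeometryError(f"lattice must be 3-D with every axis >= 1, got shape {shape}")
    return origin, spacing


@dataclass
class StructureMask:
    """A voxelised organ (rectum, PTV, ...) on a regular lattice."""

    origin: np.ndarray
    spacing: np.ndarray
    occupancy: np.ndarray
    name: str = "structure"

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        self.origin, self.spacing = _validate_lattice(
            self.origin, self.spacing, self.occupancy.shape
        )

    # -- lattice helpers -------------------------------------------------
    @property
    def voxel_volume_cc(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def n_slices(self) -> int:
        return self.occupancy.shape[2]

    def slice_centers_z(self) -> np.ndarray:
        """z coordinate (cm) of every slice centre."""
        return self.origin[2] + self.spacing[2] * np.arange(self.n_slices)

    def occupied_slices(self) -> np.ndarray:
        """Indices of slices containing at least one occupied voxel."""
        return np.nonzero(self.occupancy.any(axis=(0, 1)))[0]

    def is_empty(self) -> bool:
        return not self.occupancy.any()

    def voxel_count(self) -> int:
        return int(self.occupancy.sum())

    def same_grid(self, other: "StructureMask | DoseGrid") -> bool:
        return (
            self.occupancy.shape == other.array_shape
            and np.allclose(self.origin, other.origin)
            and np.allclose(self.spacing, other.spacing)
        )

    @property
    def array_shape(self) -> tuple[int, ...]:
        return self.occupancy.shape

    def copy(self, name: str | None = None) -> "StructureMask":
        return StructureMask(
            self.origin.copy(), self.spacing.copy(), self.occupancy.copy(),
            name if name is not None else self.name,
        )


@dataclass
class DoseGrid:
    """Planned absolute dose (Gy) per voxel, on the same lattice conventions."""

    origin: np.ndarray
    spacing: np.ndarray
    dose: np.ndarray

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        self.origin, self.spacing = _validate_lattice(self.origin, self.spacing, self.dose.shape)
        if not np.all(self.dose >= 0):
            raise GeometryError("dose must be non-negative everywhere")

    @property
    def array_shape(self) -> tuple[int, ...]:
        return self.dose.shape

    @property
    def voxel_volume_cc(self) -> float:
        return float(np.prod(self.spacing))


def require_same_grid(a: StructureMask, b: StructureMask | DoseGrid, context: str) -> None:
    if not a.same_grid(b):
        raise GeometryError(f"{context}: inputs are not on the same grid")
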
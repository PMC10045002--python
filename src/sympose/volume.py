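"""Binary voxel volumes with physical spacing and origin.

The world position of voxel index ``(i, j, k)`` is
``origin + index * spacing`` (element-wise); the origin is the *center* of
voxel ``(0, 0, 0)``.  Voxel centers, not corners, carry the geometry, which
makes reflection of a voxel across a plane well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyVolumeError


def round_half_down(t: np.ndarray) -> np.ndarray:
    """Round to nearest integer; half-grid ties go toward the negative index."""
    return np.ceil(np.asarray(t, dtype=float) - 0.5).astype(np.int64)


@dataclass
class VoxelVolume:
    occupancy: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.occupancy = np.asarray(self.occupancy).astype(bool)
        if self.occupancy.ndim != 3:
            raise ValueError("occupancy must be a 3D array")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")

    # -- basic queries ------------------------------------------------
    @property
    def shape(self) -> tuple:
        return self.occupancy.shape

    @property
    def count(self) -> int:
        return int(self.occupancy.sum())

    def require_nonempty(self) -> None:
        if self.count == 0:
            raise EmptyVolumeError("empty volume")

    def occupied_indices(self) -> np.ndarray:
        return np.argwhere(self.occupancy)

    def occupied_centers(self) -> np.ndarray:
        """World coordinates (mm) of the centers of all occupied voxels."""
        return self.index_to_world(self.occupied_indices())

    def index_to_world(self, idx) -> np.ndarray:
        return self.origin + np.asarray(idx, dtype=float) * self.spacing

    def world_to_index(self, points) -> np.ndarray:
        """Nearest voxel index of world points (ties round toward negative)."""
        t = (np.asarray(points, dtype=float) - self.origin) / self.spacing
        return round_half_down(t)

    def in_bounds(self, idx) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx))
        shape = np.asarray(self.shape)
        return np.all((idx >= 0) & (idx < shape), axis=-1)

    @property
    def grid_center(self) -> np.ndarray:
        """World coordinates of the geometric center of the voxel lattice."""
        return self.origin + (np.asarray(self.shape) - 1) / 2.0 * self.spacing

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(min, max) world coordinates of voxel centers in the grid."""
        return self.origin.copy(), self.index_to_world(np.asarray(self.shape) - 1)

    def copy(self) -> "VoxelVolume":
        return VoxelVolume(self.occupancy.copy(), self.spacing.copy(), self.origin.copy())
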
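"""Triangle surface meshes and their vertex point clouds."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class TriangleMesh:
    """Triangulated surface in world mm. Vertices are unique points."""

    vertices: np.ndarray  # (N, 3) float
    faces: np.ndarray     # (M, 3) int, indices into vertices

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")

    @classmethod
    def from_triangle_soup(cls, triangles: np.ndarray) -> "TriangleMesh":
        """Build from an (M, 3, 3) soup, deduplicating vertices by exact
        coordinate match and dropping degenerate (repeated-index) facets."""
        tri = np.asarray(triangles, dtype=float).reshape(-1, 3, 3)
        flat = tri.reshape(-1, 3)
        verts, inverse = np.unique(flat, axis=0, return_inverse=True)
        faces = inverse.reshape(-1, 3)
        ok = (
            (faces[:, 0] != faces[:, 1])
            & (faces[:, 1] != faces[:, 2])
            & (faces[:, 0] != faces[:, 2])
        )
        return cls(verts, faces[ok])

    @property
    def point_cloud(self) -> np.ndarray:
        """The dense point cloud used for superposition: the unique vertices."""
        return self.vertices

    @property
    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def transformed(self, xf) -> "TriangleMesh":
        return TriangleMesh(xf.apply(self.vertices), self.faces.copy())

    def enclosed_volume(self) -> float:
        """Signed-tetrahedron volume sum (positive for outward-oriented closed
        surfaces; absolute value returned)."""
        a = self.vertices[self.faces[:, 0]]
        b = self.vertices[self.faces[:, 1]]
        c = self.vertices[self.faces[:, 2]]
        return float(abs(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0))
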
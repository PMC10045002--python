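"""Surface extraction and planar contouring.

A volume becomes a marching-cubes surface mesh; mesh vertices are projected
onto the symmetry plane; the projected point cloud is rasterized onto a 2D
grid, gaps are closed with one 3x3 binary closing, the largest 8-connected
component is kept and its outer boundary is traced with the Moore
neighbor-tracing algorithm (clockwise wall following from the top-left-most
filled cell, terminating on Jacob's stopping criterion).  Inner holes are
discarded; the traced boundary is re-oriented counter-clockwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.draw import polygon as _fill_polygon

from .errors import DegenerateContourError, EmptyVolumeError, OpenContourError
from .geometry import PlaneFrame
from .mesh import TriangleMesh
from .volume import VoxelVolume


@dataclass
class Contour2D:
    """Ordered closed planar polyline in symmetry-plane (y, z) mm coordinates."""

    points: np.ndarray          # (m, 2)
    closed: bool = True
    raster_cell: float = 1.0    # grid pitch used to build it, mm

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if self.closed and len(self.points) < 3:
            raise DegenerateContourError("closed contour needs at least 3 points")
        if len(self.points) > 1 and np.any(
            np.all(self.points[1:] == self.points[:-1], axis=1)
        ):
            raise ValueError("contour contains immediate repeated points")
        if self.closed and _signed_area(self.points) < 0:
            self.points = self.points[::-1].copy()  # normalize counter-clockwise

    def __len__(self) -> int:
        return len(self.points)

    def to_dict(self) -> dict:
        return {"points": self.points.tolist(), "closed": self.closed,
                "raster_cell": self.raster_cell}

    @classmethod
    def from_dict(cls, d: dict) -> "Contour2D":
        return cls(np.asarray(d["points"]), d["closed"], d["raster_cell"])


def _signed_area(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


# -- surface extraction ----------------------------------------------------

def extract_mesh(vol: VoxelVolume, iso: float = 0.5) -> TriangleMesh:
    """Marching-cubes surface of the binary field at the given iso level.

    The volume is zero-padded by one voxel so every component yields a closed
    surface.  Vertices are in world mm.
    """
    if vol.count == 0:
        raise EmptyVolumeError("empty volume")
    padded = np.pad(vol.occupancy.astype(np.float32), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=iso, spacing=tuple(vol.spacing))
    verts = verts + (vol.origin - vol.spacing)  # undo the pad shift
    return TriangleMesh(verts, faces)


def project_to_plane(mesh_or_points, frame: PlaneFrame) -> np.ndarray:
    """Project mesh vertices (or raw points) into the frame's (y, z) chart."""
    pts = mesh_or_points.vertices if isinstance(mesh_or_points, TriangleMesh) \
        else np.asarray(mesh_or_points, dtype=float)
    return frame.project(pts)


# -- rasterization + Moore tracing ----------------------------------------

# Moore neighborhood in clockwise order (image rows grow downward): W first.
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


def _moore_trace(grid: np.ndarray) -> list[tuple[int, int]]:
    """Ordered boundary cells of the single foreground component in ``grid``.

    Starts at the top-left-most filled cell found by a row-major scan, walks
    clockwise around the 8-neighborhood, and stops when the start cell is
    re-entered from the starting direction (Jacob's stopping criterion).
    """
    filled = lambda c: 0 <= c[0] < grid.shape[0] and 0 <= c[1] < grid.shape[1] and grid[c]
    rs, cs = np.nonzero(grid)
    start = (int(rs[0]), int(cs[np.argmin(cs[rs == rs[0]])]))  # rows sorted by nonzero
    start_back = (start[0], start[1] - 1)  # empty by the scan order

    boundary = [start]
    cur, back = start, start_back
    first_move = None
    seen = {(cur, back)}
    while True:
        i = _MOORE.index((back[0] - cur[0], back[1] - cur[1]))
        nxt = None
        for k in range(1, 9):
            off = _MOORE[(i + k) % 8]
            cand = (cur[0] + off[0], cur[1] + off[1])
            if filled(cand):
                nxt = cand
                prev_off = _MOORE[(i + k - 1) % 8]
                new_back = (cur[0] + prev_off[0], cur[1] + prev_off[1])
                break
        if nxt is None:  # isolated single cell
            break
        move = (cur, nxt)
        if first_move is None:
            first_move = move
        elif move == first_move:
            break  # about to repeat the initial move out of the start cell
        boundary.append(nxt)
        cur, back = nxt, new_back
        if (cur, back) in seen:  # deterministic walk re-entered a prior state
            break
        seen.add((cur, back))
    if boundary[-1] == start and len(boundary) > 1:
        boundary.pop()
    return boundary


def trace_contour(points_yz, cell: float) -> Contour2D:
    """Rasterize a planar point set and trace the outer boundary of its
    largest 8-connected component."""
    pts = np.asarray(points_yz, dtype=float).reshape(-1, 2)
    if len(pts) < 3:
        raise DegenerateContourError("degenerate contour: fewer than 3 input points")
    pad = 2  # cells of empty margin; >= closing footprint radius
    lo = pts.min(axis=0) - pad * cell
    ij = np.floor((pts - lo) / cell).astype(int)
    shape = tuple(ij.max(axis=0) + 1 + pad)
    grid = np.zeros(shape, dtype=bool)
    grid[tuple(ij.T)] = True
    grid = ndimage.binary_closing(grid, structure=np.ones((3, 3), dtype=bool))
    labels, n = ndimage.label(grid, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        raise DegenerateContourError("degenerate contour: empty raster")
    largest = 1 + int(np.argmax(ndimage.sum_labels(grid, labels, range(1, n + 1))))
    comp = labels == largest
    if comp.sum() < 3:
        raise DegenerateContourError("degenerate contour: fewer than 3 raster cells")
    cells = _moore_trace(comp)
    centers = lo + (np.asarray(cells, dtype=float) + 0.5) * cell
    return Contour2D(centers, closed=True, raster_cell=float(cell))


# -- areas -----------------------------------------------------------------

def contour_area(c: Contour2D) -> float:
    """Shoelace area of a closed contour, mm^2."""
    if not c.closed:
        raise OpenContourError("open contour")
    return abs(_signed_area(c.points))


def overlap_area(a, b, pitch: float | None = None) -> float:
    """Rasterized intersection area of two closed polygons, mm^2.

    Each polygon is filled on a common grid at ``pitch`` (default: half the
    finer raster cell) and the intersecting cell count is converted to area.
    Accepts Contour2D or raw (m, 2) vertex arrays.
    """
    pa, ca = _polygon_points(a)
    pb, cb = _polygon_points(b)
    if pitch is None:
        pitch = min(ca, cb) / 2.0
    lo = np.minimum(pa.min(axis=0), pb.min(axis=0)) - pitch
    hi = np.maximum(pa.max(axis=0), pb.max(axis=0)) + pitch
    shape = tuple(np.ceil((hi - lo) / pitch).astype(int) + 1)

    def fill(p):
        rr, cc = _fill_polygon((p[:, 0] - lo[0]) / pitch, (p[:, 1] - lo[1]) / pitch, shape)
        g = np.zeros(shape, dtype=bool)
        g[rr, cc] = True
        return g

    return float((fill(pa) & fill(pb)).sum()) * pitch * pitch


def _polygon_points(c) -> tuple[np.ndarray, float]:
    if isinstance(c, Contour2D):
        if not c.closed:
            raise OpenContourError("open contour")
        return c.points, c.raster_cell
    return np.asarray(c, dtype=float).reshape(-1, 2), 1.0
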
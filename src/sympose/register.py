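"""Iterative contour registration in the symmetry plane, plus a 3D ICP baseline.

The planar registration alternates (i) nearest-neighbor correspondences from
the fixed contour A to the moving contour B through a K-D tree, and (ii) a
closed-form rigid fit: with centroid-reduced matched points, the covariance
H = sum(b_bar a_bar^T) is decomposed H = U Lambda V^T and R = V U^T; if
det(R) = -1 the smaller singular direction is flipped, R = V diag(1,-1) U^T,
so the returned rotation is always proper.  The translation is
t = a_bar - R b_bar and the residual is E = sum |R b_j + t - a_i|.
Convergence tracks the overlap area of the two contours: the iteration stops
when the area changes by less than ``area_tol`` (default 0.001 mm^2) between
two iterations, with a secondary guard on a vanishing residual change to
catch raster plateaus.  The converged in-plane motion is lifted to a 3D rigid
transform that fixes the plane normal and is composed after the initial
superposition.

``icp_3d`` is the classic point-to-point ICP baseline (K-D tree nearest
neighbors, 3D Kabsch/SVD with determinant correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .contour import Contour2D, overlap_area
from .errors import DegenerateCorrespondenceError
from .geometry import PlaneFrame, RigidTransform


@dataclass
class RegistrationResult:
    transform_2d: tuple | None          # (rotation 2x2, translation (2,)) cumulative
    transform_3d: RigidTransform | None
    residual_E: float                   # sum of correspondence distances at the end
    rms: float                          # RMS correspondence distance at the end
    overlap_area: float | None
    iterations: int
    converged: bool
    per_iteration: list = field(default_factory=list)  # (E, overlap_area) per iteration

    @property
    def rotation_angle_deg(self) -> float:
        r = self.transform_2d[0]
        return float(np.degrees(np.arctan2(r[1, 0], r[0, 0])))


def correspondences(a, b) -> np.ndarray:
    """(i, j) pairs: for every point of A, its nearest point of B (K-D tree).

    Every point of A is matched (no rejection); distance ties resolve to the
    smallest index j.
    """
    pa, pb = _points(a), _points(b)
    tree = cKDTree(pb)
    if len(pb) == 1:
        return np.column_stack([np.arange(len(pa)), np.zeros(len(pa), dtype=int)])
    dist, j = tree.query(pa, k=2)
    jj = j[:, 0].copy()
    # exact-distance ties resolve to the smallest index j
    for row in np.flatnonzero(np.isclose(dist[:, 0], dist[:, 1], rtol=1e-12, atol=1e-12)):
        cand = tree.query_ball_point(pa[row], dist[row, 0] * (1 + 1e-12) + 1e-300)
        jj[row] = min(cand)
    return np.column_stack([np.arange(len(pa)), jj])


def _points(c) -> np.ndarray:
    return c.points if isinstance(c, Contour2D) else np.asarray(c, dtype=float)


def polyline_closest_points(a_pts: np.ndarray, b_pts: np.ndarray) -> np.ndarray:
    """For each point of A, the closest point on the closed polyline through B.

    Vertex matching on uniformly spaced closed curves has stable fixed points
    at half-pitch tangential offsets; projecting onto the polyline's segments
    removes that raster lock.  Exhaustive over segments (contours are small).
    """
    p0 = b_pts
    d = np.roll(b_pts, -1, axis=0) - b_pts          # (m_b, 2) closed segments
    len2 = np.maximum((d * d).sum(axis=1), 1e-300)
    diff = a_pts[:, None, :] - p0[None, :, :]        # (m_a, m_b, 2)
    t = np.clip(np.einsum("abk,bk->ab", diff, d) / len2, 0.0, 1.0)
    proj = p0[None, :, :] + t[:, :, None] * d[None, :, :]
    dist2 = ((a_pts[:, None, :] - proj) ** 2).sum(axis=2)
    best = np.argmin(dist2, axis=1)
    return proj[np.arange(len(a_pts)), best]


def svd_rigid_2d(a_pts, b_pts) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares proper rotation + translation mapping b onto a.

    Returns (R, t, E) with det(R) = +1 always and E = sum |R b + t - a|.
    """
    a = np.asarray(a_pts, dtype=float).reshape(-1, 2)
    b = np.asarray(b_pts, dtype=float).reshape(-1, 2)
    if len(a) < 2 or len(a) != len(b):
        raise ValueError("need >= 2 matched pairs of equal count")
    abar, bbar = a.mean(axis=0), b.mean(axis=0)
    ac, bc = a - abar, b - bbar
    if np.allclose(ac, 0.0) and np.allclose(bc, 0.0):
        raise DegenerateCorrespondenceError("degenerate correspondence set")
    h = bc.T @ ac  # so that R = V U^T maps b onto a (minimizes Eq-8-style residual)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, d if d != 0 else 1.0]) @ u.T  # reflection correction
    t = abar - r @ bbar
    e = float(np.linalg.norm(b @ r.T + t - a, axis=1).sum())
    return r, t, e


def register_contours(
    a: Contour2D,
    b: Contour2D,
    area_tol: float = 0.001,
    max_iter: int = 200,
    residual_tol: float = 1e-9,
    polish: bool = True,
) -> RegistrationResult:
    """Iterative in-plane registration of contour B onto contour A.

    The main loop matches contour cells (K-D tree) and stops on the overlap
    area criterion.  With ``polish`` (default), a sub-raster refinement phase
    then re-matches each A point against B's continuous polyline and repeats
    the rigid fit until the residual stalls; this removes the half-pitch
    tangential lock of pure cell matching and brings identical shapes into
    exact alignment.  Non-convergence at ``max_iter`` is reported via
    ``converged=False``, not raised.
    """
    pa = a.points
    pb = b.points.copy()
    r_cum, t_cum = np.eye(2), np.zeros(2)
    per_iter: list[tuple[float, float]] = []
    converged = False
    prev_area = None
    prev_e = None
    pitch = min(a.raster_cell, b.raster_cell) / 2.0

    it = 0
    for it in range(1, max_iter + 1):
        pairs = correspondences(pa, pb)
        r, t, e = svd_rigid_2d(pa[pairs[:, 0]], pb[pairs[:, 1]])
        pb = pb @ r.T + t
        r_cum, t_cum = r @ r_cum, r @ t_cum + t
        area = overlap_area(pa, pb, pitch=pitch)
        per_iter.append((e, area))
        if prev_area is not None and abs(area - prev_area) < area_tol:
            converged = True
            break
        if prev_e is not None and abs(e - prev_e) < residual_tol:
            converged = True  # residual plateau: motion has stopped
            break
        prev_area, prev_e = area, e

    if polish:
        prev_e = None
        for _ in range(50):
            if it >= max_iter:
                break
            q = polyline_closest_points(pa, pb)
            r, t, e = svd_rigid_2d(pa, q)
            pb = pb @ r.T + t
            r_cum, t_cum = r @ r_cum, r @ t_cum + t
            it += 1
            per_iter.append((e, overlap_area(pa, pb, pitch=pitch)))
            if prev_e is not None and abs(e - prev_e) < residual_tol:
                break
            prev_e = e

    dist, _ = cKDTree(pb).query(pa)
    return RegistrationResult(
        transform_2d=(r_cum, t_cum),
        transform_3d=None,
        residual_E=per_iter[-1][0] if per_iter else 0.0,
        rms=float(np.sqrt(np.mean(dist**2))),
        overlap_area=per_iter[-1][1] if per_iter else None,
        iterations=it,
        converged=converged,
        per_iteration=per_iter,
    )


def lift_to_3d(
    result: RegistrationResult,
    frame_a: PlaneFrame,
    x_init: RigidTransform,
) -> RigidTransform:
    """Embed the cumulative in-plane motion as a 3D rigid transform that fixes
    the plane normal of ``frame_a``, composed after the initial superposition.

    For on-plane points p, ``project(lift(p)) == apply_2d(project(p))``.
    """
    r2, t2 = result.transform_2d
    basis = np.column_stack([frame_a.normal, frame_a.axis_y, frame_a.axis_z])
    r3f = np.eye(3)
    r3f[1:, 1:] = r2
    r3 = basis @ r3f @ basis.T
    t3 = basis @ np.array([0.0, t2[0], t2[1]]) + frame_a.origin - r3 @ frame_a.origin
    inplane = RigidTransform.from_rotation_translation(r3, t3)
    lifted = inplane @ x_init
    result.transform_3d = lifted
    return lifted


def kabsch_3d(a_pts, b_pts) -> tuple[np.ndarray, np.ndarray]:
    """Proper 3D rotation + translation mapping b onto a (least squares)."""
    a = np.asarray(a_pts, dtype=float).reshape(-1, 3)
    b = np.asarray(b_pts, dtype=float).reshape(-1, 3)
    abar, bbar = a.mean(axis=0), b.mean(axis=0)
    ac, bc = a - abar, b - bbar
    if np.allclose(ac, 0.0) and np.allclose(bc, 0.0):
        raise DegenerateCorrespondenceError("degenerate correspondence set")
    h = bc.T @ ac
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d if d != 0 else 1.0]) @ u.T
    return r, abar - r @ bbar


def icp_3d(
    src,
    dst,
    max_iter: int = 200,
    tol: float = 1e-6,
    max_points: int | None = None,
) -> RegistrationResult:
    """Classic point-to-point ICP registering the ``src`` cloud onto ``dst``.

    Stops when the mean correspondence distance changes by less than ``tol``
    mm.  ``max_points`` subsamples the source deterministically (uniform
    stride) for speed; the returned transform still applies to the full cloud.
    """
    src = np.asarray(src, dtype=float).reshape(-1, 3)
    dst = np.asarray(dst, dtype=float).reshape(-1, 3)
    if len(src) < 3 or len(dst) < 3:
        raise DegenerateCorrespondenceError("degenerate correspondence set")
    if max_points is not None and len(src) > max_points:
        stride = int(np.ceil(len(src) / max_points))
        src = src[::stride]

    tree = cKDTree(dst)
    moved = src.copy()
    r_cum, t_cum = np.eye(3), np.zeros(3)
    per_iter: list[tuple[float, None]] = []
    converged = False
    prev = None
    it = 0
    for it in range(1, max_iter + 1):
        dist, j = tree.query(moved)
        mean_res = float(dist.mean())
        per_iter.append((mean_res, None))
        if prev is not None and abs(prev - mean_res) < tol:
            converged = True
            break
        prev = mean_res
        r, t = kabsch_3d(dst[j], moved)
        moved = moved @ r.T + t
        r_cum, t_cum = r @ r_cum, r @ t_cum + t

    dist, _ = tree.query(moved)
    return RegistrationResult(
        transform_2d=None,
        transform_3d=RigidTransform.from_rotation_translation(r_cum, t_cum),
        residual_E=float(dist.sum()),
        rms=float(np.sqrt(np.mean(dist**2))),
        overlap_area=None,
        iterations=it,
        converged=converged,
        per_iteration=per_iter,
    )
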
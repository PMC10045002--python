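"""Geometric primitives shared across the pipeline.

Conventions
-----------
* All coordinates are world millimetres.
* :class:`RigidTransform` uses the column-vector homogeneous convention,
  ``p' = M @ [p; 1]``, so composition reads right to left.
* :class:`Plane` is stored as a unit normal plus signed offset,
  ``{p : normal . p = offset}``, with a canonical sign (the largest-magnitude
  normal component is positive, ties broken by the first axis) so two
  parameterisations of the same plane compare equal.
"""

from __future__ import annotations

import numpy as np

from .errors import NotRigidError

ORTHO_TOL = 1e-9


def unit(v: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Return ``v`` normalized to unit length; raise on (near-)zero vectors."""
    v = np.asarray(v, dtype=float)
    n = float(np.linalg.norm(v))
    if n < tol:
        raise ValueError("cannot normalize a zero-length vector")
    return v / n


class Plane:
    """Oriented plane ``{p : normal . p = offset}`` in world mm."""

    __slots__ = ("normal", "offset")

    def __init__(self, normal, offset: float):
        n = unit(normal)
        k = int(np.argmax(np.abs(n)))  # argmax -> first axis on ties
        offset = float(offset)
        if n[k] < 0:
            n, offset = -n, -offset
        self.normal = n
        self.normal.setflags(write=False)
        self.offset = offset

    def __repr__(self) -> str:
        return f"Plane(normal={self.normal.tolist()}, offset={self.offset:.6g})"

    def signed_distance(self, points) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.normal - self.offset

    def mirror(self, points) -> np.ndarray:
        """Reflect points across the plane: p - 2 (n.p - d) n."""
        points = np.asarray(points, dtype=float)
        d = self.signed_distance(points)
        return points - 2.0 * np.multiply.outer(d, self.normal)

    def transformed(self, xf: "RigidTransform") -> "Plane":
        n = xf.rotation @ self.normal
        return Plane(n, self.offset + n @ xf.translation)

    def angle_deg_to(self, other: "Plane") -> float:
        """Unsigned angle between plane normals in degrees (orientation-free)."""
        c = abs(float(self.normal @ other.normal))
        return float(np.degrees(np.arccos(min(1.0, c))))

    def to_dict(self) -> dict:
        return {"normal": self.normal.tolist(), "offset": self.offset}

    @classmethod
    def from_dict(cls, d: dict) -> "Plane":
        return cls(d["normal"], d["offset"])


class RigidTransform:
    """4x4 homogeneous proper rigid map, column-vector convention."""

    __slots__ = ("matrix",)

    def __init__(self, matrix):
        m = np.asarray(matrix, dtype=float)
        if m.shape != (4, 4):
            raise NotRigidError("not a rigid transform: expected a 4x4 matrix")
        r = m[:3, :3]
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-8):
            raise NotRigidError("not a rigid transform: rotation block not orthonormal")
        if np.linalg.det(r) < 0.0:
            raise NotRigidError("not a rigid transform: improper rotation (det -1)")
        if not np.allclose(m[3], (0.0, 0.0, 0.0, 1.0), atol=1e-9):
            raise NotRigidError("not a rigid transform: last row must be (0,0,0,1)")
        self.matrix = m
        self.matrix.setflags(write=False)

    # -- constructors -------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_rotation_translation(cls, rotation, translation) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = np.asarray(rotation, dtype=float)
        m[:3, 3] = np.asarray(translation, dtype=float)
        return cls(m)

    @classmethod
    def from_translation(cls, translation) -> "RigidTransform":
        return cls.from_rotation_translation(np.eye(3), translation)

    @classmethod
    def from_axis_angle(cls, axis, angle_deg: float, center=None) -> "RigidTransform":
        """Rotation of ``angle_deg`` about ``axis`` through ``center`` (default origin)."""
        from scipy.spatial.transform import Rotation

        r = Rotation.from_rotvec(np.radians(angle_deg) * unit(axis)).as_matrix()
        if center is None:
            return cls.from_rotation_translation(r, np.zeros(3))
        c = np.asarray(center, dtype=float)
        return cls.from_rotation_translation(r, c - r @ c)

    # -- algebra ------------------------------------------------------
    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self @ other)(p) = self(other(p))."""
        return RigidTransform(self.matrix @ other.matrix)

    __matmul__ = compose

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform.from_rotation_translation(rt, -rt @ self.translation)

    def apply(self, points) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        single = points.ndim == 1
        pts = np.atleast_2d(points)
        out = pts @ self.rotation.T + self.translation
        return out[0] if single else out

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, in degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    def is_close(self, other: "RigidTransform", atol: float = 1e-9) -> bool:
        return bool(np.allclose(self.matrix, other.matrix, atol=atol))

    def to_dict(self) -> dict:
        return {"matrix": self.matrix.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(d["matrix"])

    def __repr__(self) -> str:
        return f"RigidTransform(angle={self.rotation_angle_deg():.3f} deg, t={self.translation.tolist()})"


class PlaneFrame:
    """A 2D chart on a plane: origin + two in-plane axes + the plane normal.

    In-plane coordinates are ``(y, z) = ((p - origin) . axis_y, (p - origin) . axis_z)``.
    The triple ``(normal, axis_y, axis_z)`` is right-handed orthonormal.
    """

    __slots__ = ("origin", "axis_y", "axis_z", "normal")

    def __init__(self, origin, axis_y, axis_z, normal):
        o = np.asarray(origin, dtype=float)
        ay, az, n = unit(axis_y), unit(axis_z), unit(normal)
        g = np.column_stack([n, ay, az])
        if not np.allclose(g.T @ g, np.eye(3), atol=1e-9):
            raise ValueError("frame axes must be orthonormal")
        if np.linalg.det(g) < 0.0:
            raise ValueError("frame must be right-handed: (normal, axis_y, axis_z)")
        self.origin, self.axis_y, self.axis_z, self.normal = o, ay, az, n
        for a in (self.origin, self.axis_y, self.axis_z, self.normal):
            a.setflags(write=False)

    @property
    def plane(self) -> Plane:
        return Plane(self.normal, self.normal @ self.origin)

    def project(self, points) -> np.ndarray:
        """World (N,3) -> in-plane (N,2). Kills the normal component."""
        points = np.atleast_2d(np.asarray(points, dtype=float)) - self.origin
        return np.column_stack([points @ self.axis_y, points @ self.axis_z])

    def embed(self, yz) -> np.ndarray:
        """In-plane (N,2) -> world (N,3) points lying on the plane."""
        yz = np.atleast_2d(np.asarray(yz, dtype=float))
        return self.origin + np.outer(yz[:, 0], self.axis_y) + np.outer(yz[:, 1], self.axis_z)

    def to_dict(self) -> dict:
        return {
            "origin": self.origin.tolist(),
            "axis_y": self.axis_y.tolist(),
            "axis_z": self.axis_z.tolist(),
            "normal": self.normal.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlaneFrame":
        return cls(d["origin"], d["axis_y"], d["axis_z"], d["normal"])
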
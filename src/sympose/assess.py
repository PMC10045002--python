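"""Superposition quality and surgical-precision metrics.

Deviation between two superimposed objects is the mean closest-point
distance from the moved cloud to the reference cloud (direction fixed as
moved -> reference), reported over the whole object and over the
vertebral-body subset when a mask is supplied.

Screw-trajectory precision compares a planned and an achieved trajectory
(entry point + unit direction) in three views defined by a local anatomical
frame: 3D, "horizontal" (the plane normal to the local z, superior-inferior,
axis) and "sagittal" (the symmetry plane itself, normal = local x):

* DD / HDD / SDD - entry-point distance in 3D and projected into the two views;
* DA / HDA / SDA - angle between the trajectory directions in 3D and after
  projection into the two views (absolute angles, so HDA/SDA are in [0, 90]).

A direction that projects to (near) zero length in a view leaves that view's
angle undefined; the report flags it instead of inventing a number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import PlaneFrame, unit


@dataclass
class Trajectory:
    entry: np.ndarray      # world mm
    direction: np.ndarray  # unit 3-vector

    def __post_init__(self):
        self.entry = np.asarray(self.entry, dtype=float).reshape(3)
        d = np.asarray(self.direction, dtype=float).reshape(3)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValueError("trajectory direction must be a unit vector")
        self.direction = d

    @classmethod
    def from_vector(cls, entry, direction) -> "Trajectory":
        return cls(entry, unit(direction))

    def to_dict(self) -> dict:
        return {"entry": self.entry.tolist(), "direction": self.direction.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Trajectory":
        return cls(d["entry"], d["direction"])


@dataclass
class DeviationReport:
    mean_full: float
    mean_body: float | None          # None when the subset mask is empty
    body_undefined: bool = False
    per_point: np.ndarray | None = None
    direction: str = "moved->reference"


@dataclass
class TrajectoryReport:
    dd: float
    hdd: float
    sdd: float
    da_deg: float
    hda_deg: float | None
    sda_deg: float | None
    undefined: tuple = ()

    def to_dict(self) -> dict:
        return {"DD": self.dd, "HDD": self.hdd, "SDD": self.sdd,
                "DA": self.da_deg, "HDA": self.hda_deg, "SDA": self.sda_deg,
                "undefined": list(self.undefined)}


def closest_point_deviation(
    moved,
    reference,
    subset_mask=None,
    keep_per_point: bool = False,
) -> DeviationReport:
    """Mean nearest-neighbor distance from each moved point to the reference
    cloud, over all points and over the ``subset_mask`` subset."""
    moved = np.asarray(moved, dtype=float).reshape(-1, 3)
    reference = np.asarray(reference, dtype=float).reshape(-1, 3)
    if len(moved) == 0 or len(reference) == 0:
        raise ValueError("both clouds must be non-empty")
    dist, _ = cKDTree(reference).query(moved)
    mean_body, undefined = None, False
    if subset_mask is not None:
        subset_mask = np.asarray(subset_mask, dtype=bool).reshape(-1)
        if subset_mask.sum() == 0:
            undefined = True
        else:
            mean_body = float(dist[subset_mask].mean())
    return DeviationReport(
        mean_full=float(dist.mean()),
        mean_body=mean_body,
        body_undefined=undefined,
        per_point=dist if keep_per_point else None,
    )


def _view_angle(u: np.ndarray, v: np.ndarray, view_normal: np.ndarray):
    """Absolute angle (deg) between two directions projected into the plane
    normal to ``view_normal``; None when a projection (nearly) vanishes."""
    up = u - (u @ view_normal) * view_normal
    vp = v - (v @ view_normal) * view_normal
    if np.linalg.norm(up) < 1e-6 or np.linalg.norm(vp) < 1e-6:
        return None
    c = abs(float(unit(up) @ unit(vp)))
    return float(np.degrees(np.arccos(min(1.0, c))))


def trajectory_deviation(
    plan: Trajectory,
    outcome: Trajectory,
    frame: PlaneFrame,
) -> TrajectoryReport:
    """Entry-point and angular deviations in 3D, horizontal and sagittal views."""
    delta = plan.entry - outcome.entry
    z, x = frame.axis_z, frame.normal
    dd = float(np.linalg.norm(delta))
    hdd = float(np.linalg.norm(delta - (delta @ z) * z))
    sdd = float(np.linalg.norm(delta - (delta @ x) * x))
    da = float(np.degrees(np.arccos(np.clip(plan.direction @ outcome.direction, -1.0, 1.0))))
    hda = _view_angle(plan.direction, outcome.direction, z)
    sda = _view_angle(plan.direction, outcome.direction, x)
    undefined = tuple(name for name, val in (("HDA", hda), ("SDA", sda)) if val is None)
    return TrajectoryReport(dd=dd, hdd=hdd, sdd=sdd, da_deg=da,
                            hda_deg=hda, sda_deg=sda, undefined=undefined)


def compare_methods(
    references,
    moved_by_method,
    subset_masks=None,
    labels=("osp", "icp"),
) -> pd.DataFrame:
    """Side-by-side deviation table for two registration methods.

    ``references`` is a list of reference clouds (one per pre/post pair);
    ``moved_by_method`` maps each label to the list of registered (moved)
    clouds; ``subset_masks`` optionally restricts the body columns.  One row
    per input pair.
    """
    n = len(references)
    rows = []
    for i in range(n):
        row: dict = {"pair": i}
        for label in labels:
            mask = subset_masks[i] if subset_masks is not None else None
            rep = closest_point_deviation(moved_by_method[label][i], references[i], mask)
            row[f"{label}_mean_full"] = rep.mean_full
            row[f"{label}_mean_body"] = rep.mean_body
        rows.append(row)
    return pd.DataFrame(rows)
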
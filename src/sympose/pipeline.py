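"""End-to-end pipeline: simulate -> osp -> contour -> init -> register -> assess.

A single seeded configuration drives every stage; identical seed + config
reproduce the summary bit-identically.  Per-stage artifacts (volumes, meshes,
planes, transforms, contours, reports) are written so each stage can be
re-loaded and inspected on its own.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from . import io
from .assess import Trajectory, closest_point_deviation, compare_methods, trajectory_deviation
from .contour import project_to_plane, trace_contour
from .errors import ConfigError
from .geometry import RigidTransform
from .osp import OspConfig, find_osp
from .phantom import make_phantom_pair
from .register import icp_3d, lift_to_3d, register_contours
from .superpose import initial_superposition


@dataclass
class RunConfig:
    seed: int = 0
    grid: int = 48
    spacing: float = 0.7
    asymmetry_amplitude: float = 0.5       # mm
    lamina_removal_fraction: float = 0.25
    artifact_blob_count: int = 6
    max_rotation_deg: float = 8.0
    max_translation_mm: float = 4.0
    gamma: float = 0.4                     # posterior band fraction
    k: int = 0                             # bending half-width; 0 -> auto
    bv_threshold: float = 1.8
    bv_threshold_mode: str = "normalized"  # or "scaled_by_k" (threshold * k)
    contour_cell: float = 0.0              # mm; 0 -> min voxel spacing
    area_tol: float = 0.001                # mm^2 convergence criterion
    max_iter: int = 200
    osp_restarts: int = 4
    icp_max_points: int = 4000

    def validate(self) -> None:
        if not 0.0 < self.gamma <= 1.0:
            raise ConfigError(f"gamma must be in (0, 1], got {self.gamma}")
        if self.area_tol <= 0:
            raise ConfigError("area_tol must be positive")
        if self.max_iter < 1:
            raise ConfigError("max_iter must be >= 1")
        if not 0.0 <= self.lamina_removal_fraction <= 1.0:
            raise ConfigError("lamina_removal_fraction must be in [0, 1]")
        if self.bv_threshold_mode not in ("normalized", "scaled_by_k"):
            raise ConfigError(f"unknown bv_threshold_mode {self.bv_threshold_mode!r}")
        if self.grid < 16:
            raise ConfigError("grid must be >= 16")
        if self.spacing <= 0:
            raise ConfigError("spacing must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name: f.type for f in dataclasses.fields(cls)}
        unknown = set(d) - set(known)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Parse a flat ``key = value`` text file (# starts a comment)."""
        d: dict = {}
        types = {f.name: f.default for f in dataclasses.fields(cls)}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"malformed config line: {line!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in types:
                raise ConfigError(f"unknown config keys: [{key!r}]")
            default = types[key]
            d[key] = val if isinstance(default, str) else type(default)(float(val)) \
                if isinstance(default, (int, float)) and not isinstance(default, bool) else val
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _classify_body_vertices(mesh_points: np.ndarray, phantom) -> np.ndarray:
    """True for mesh vertices nearer to body voxels than to any other
    foreground voxel (posterior elements or artifacts)."""
    body_pts = phantom.volume.index_to_world(np.argwhere(phantom.body_mask))
    other = phantom.posterior_mask | phantom.artifact_mask
    other_pts = phantom.volume.index_to_world(np.argwhere(other))
    if len(other_pts) == 0:
        return np.ones(len(mesh_points), dtype=bool)
    d_body, _ = cKDTree(body_pts).query(mesh_points)
    d_other, _ = cKDTree(other_pts).query(mesh_points)
    return d_body <= d_other


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute all stages on a simulated pre/post pair; returns the summary
    dict (also written to ``outdir/summary.json``)."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cell = config.contour_cell or config.spacing
    k = config.k or None

    # -- simulate ---------------------------------------------------------
    pre, post, true_xf = make_phantom_pair(
        config.seed,
        grid_shape=(config.grid,) * 3,
        spacing=(config.spacing,) * 3,
        asymmetry_amplitude=config.asymmetry_amplitude,
        lamina_removal_fraction=config.lamina_removal_fraction,
        artifact_blob_count=config.artifact_blob_count,
        max_rotation_deg=config.max_rotation_deg,
        max_translation_mm=config.max_translation_mm,
    )
    io.write_volume(pre.volume, outdir / "pre.nrrd")
    io.write_volume(post.volume, outdir / "post.nrrd")
    pre.write_ground_truth(outdir / "pre_truth.json")
    post.write_ground_truth(outdir / "post_truth.json")

    # -- osp --------------------------------------------------------------
    osp_cfg = OspConfig(restarts=config.osp_restarts)
    osp_a = find_osp(pre.volume, osp_cfg)
    osp_b = find_osp(post.volume, osp_cfg)
    io.save_json(osp_a.plane, outdir / "plane_pre.json", score=osp_a.score)
    io.save_json(osp_b.plane, outdir / "plane_post.json", score=osp_b.score)

    # -- contour + init ---------------------------------------------------
    from .contour import extract_mesh

    mesh_a = extract_mesh(pre.volume)
    mesh_b = extract_mesh(post.volume)
    io.write_stl(mesh_a, outdir / "pre.stl")
    io.write_stl(mesh_b, outdir / "post.stl")
    init = initial_superposition(
        mesh_a, osp_a.plane, mesh_b, osp_b.plane,
        cell=cell, k=k, gamma=config.gamma,
        threshold=config.bv_threshold, threshold_mode=config.bv_threshold_mode,
    )
    io.save_json(init.transform, outdir / "init_transform.json")

    # -- register (symmetry-plane contour method) -------------------------
    b_init = init.transform.apply(mesh_b.point_cloud)
    contour_a = init.contour_a
    contour_b = trace_contour(project_to_plane(b_init, init.frame_a), cell)
    reg = register_contours(contour_a, contour_b,
                            area_tol=config.area_tol, max_iter=config.max_iter)
    osp_xf = lift_to_3d(reg, init.frame_a, init.transform)
    io.save_json(osp_xf, outdir / "osp_transform.json")

    # -- register (ICP baseline) ------------------------------------------
    icp = icp_3d(mesh_b.point_cloud, mesh_a.point_cloud,
                 max_iter=config.max_iter, max_points=config.icp_max_points)
    io.save_json(icp.transform_3d, outdir / "icp_transform.json")

    # -- assess -----------------------------------------------------------
    body_mask_b = _classify_body_vertices(mesh_b.point_cloud, post)
    moved = {
        "osp": [osp_xf.apply(mesh_b.point_cloud)],
        "icp": [icp.transform_3d.apply(mesh_b.point_cloud)],
    }
    table = compare_methods([mesh_a.point_cloud], moved, [body_mask_b])
    table.to_csv(outdir / "deviations.csv", index=False)

    def xf_error(xf: RigidTransform) -> dict:
        err = xf @ true_xf  # perfect recovery would be the identity
        return {"rotation_deg": err.rotation_angle_deg(),
                "translation_mm": float(np.linalg.norm(
                    err.apply(post.volume.grid_center) - post.volume.grid_center))}

    # trajectory demo: a planned screw vs its achieved pose mapped back
    rng = np.random.default_rng(config.seed + 77)
    plan = Trajectory.from_vector(pre.volume.grid_center, (0.2, -0.8, 0.1))
    achieved_dir = plan.direction + rng.normal(0.0, 0.05, 3)
    achieved_entry = plan.entry + rng.normal(0.0, 1.0, 3)
    outcome_world_b = Trajectory.from_vector(true_xf.apply(achieved_entry),
                                             true_xf.rotation @ (achieved_dir / np.linalg.norm(achieved_dir)))
    outcome_back = Trajectory.from_vector(osp_xf.apply(outcome_world_b.entry),
                                          osp_xf.rotation @ outcome_world_b.direction)
    frame_pre = init.frame_a
    traj = trajectory_deviation(plan, outcome_back, frame_pre)

    dev_osp = closest_point_deviation(moved["osp"][0], mesh_a.point_cloud, body_mask_b)
    dev_icp = closest_point_deviation(moved["icp"][0], mesh_a.point_cloud, body_mask_b)

    summary = {
        "config": config.to_dict(),
        "osp": {
            "pre_score": osp_a.score, "post_score": osp_b.score,
            "pre_plane": osp_a.plane.to_dict(), "post_plane": osp_b.plane.to_dict(),
            "pre_angle_error_deg": osp_a.plane.angle_deg_to(pre.true_plane),
            "post_angle_error_deg": osp_b.plane.angle_deg_to(post.true_plane),
        },
        "registration": {
            "iterations": reg.iterations, "converged": reg.converged,
            "residual_E_mm": reg.residual_E, "rms_mm": reg.rms,
            "overlap_area_mm2": reg.overlap_area,
            "transform_error": xf_error(osp_xf),
        },
        "icp": {
            "iterations": icp.iterations, "converged": icp.converged,
            "rms_mm": icp.rms, "transform_error": xf_error(icp.transform_3d),
        },
        "deviation_mm": {
            "osp_full": dev_osp.mean_full, "osp_body": dev_osp.mean_body,
            "icp_full": dev_icp.mean_full, "icp_body": dev_icp.mean_body,
        },
        "trajectory": traj.to_dict(),
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
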
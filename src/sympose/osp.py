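"""Optimal symmetry plane (OSP) search.

The degree of asymmetry of a binary volume about a plane is the fraction of
occupied voxels whose mirror image (reflection of the voxel center, rounded
to the nearest voxel) does not land on an occupied in-grid voxel:

    f = 1 - paired / total,   0 <= f <= 1,

so f = 0 for a perfectly mirror-symmetric object.  The OSP is the plane
minimizing f.  The objective is piecewise constant in the plane parameters
(voxel rounding), so the search is derivative-free: a coarse angular/offset
scan around the mid-grid sagittal initial guess followed by Nelder-Mead with
a handful of perturbed restarts.  The pairing relation is one-directional
(a voxel may be paired while its mirror partner is not).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .geometry import Plane
from .volume import VoxelVolume, round_half_down


@dataclass
class SymmetryResult:
    plane: Plane
    score: float
    paired_count: int
    total_count: int
    optimizer_trace: list = field(default_factory=list)
    warning: bool = False  # set when the optimizer failed to improve

    def __post_init__(self):
        assert 0.0 <= self.score <= 1.0


@dataclass
class OspConfig:
    restarts: int = 4                 # Nelder-Mead restarts from +/-5 deg perturbations
    coarse_scan: bool = True          # 5 deg x 5 deg x 1-voxel scan before refinement
    scan_half_angle_deg: float = 15.0
    scan_step_deg: float = 5.0
    scan_offset_steps: int = 3        # +/- this many voxels of offset in the scan
    fatol: float = 1e-5               # simplex score spread at convergence
    max_evals: int = 400              # per Nelder-Mead run
    multiresolution: bool = False     # coarse-to-fine x4 -> x2 -> x1
    trace: bool = False               # record (params, score) evaluations


def _plane_from_params(params) -> Plane:
    """(azimuth, elevation, offset) -> plane; (0, 0, d) is the x-normal plane."""
    az, el, offset = params
    n = np.array([np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)])
    return Plane(n, offset)


def symmetry_score(vol: VoxelVolume, plane: Plane) -> SymmetryResult:
    """Evaluate the unpaired-voxel objective f for one plane."""
    vol.require_nonempty()
    centers = vol.occupied_centers()
    mirrored = plane.mirror(centers)
    idx = round_half_down((mirrored - vol.origin) / vol.spacing)
    shape = np.asarray(vol.shape)
    inside = np.all((idx >= 0) & (idx < shape), axis=1)
    paired = int(vol.occupancy[tuple(idx[inside].T)].sum())
    total = len(centers)
    return SymmetryResult(
        plane=plane,
        score=1.0 - paired / total,
        paired_count=paired,
        total_count=total,
    )


def grid_search_osp(
    vol: VoxelVolume,
    half_angle_deg: float = 15.0,
    step_deg: float = 5.0,
    offset_steps: int = 1,
) -> SymmetryResult:
    """Exhaustive coarse scan over (azimuth, elevation, offset) around the
    mid-grid x-normal plane; offsets step by one (minimum) voxel spacing.
    Serves both as the optimizer's warm start and as an independent oracle."""
    vol.require_nonempty()
    d0 = float(vol.grid_center[0])
    step_off = float(vol.spacing.min())
    angles = np.radians(np.arange(-half_angle_deg, half_angle_deg + 1e-9, step_deg))
    offsets = d0 + step_off * np.arange(-offset_steps, offset_steps + 1)
    best = None
    for az in angles:
        for el in angles:
            for d in offsets:
                r = symmetry_score(vol, _plane_from_params((az, el, d)))
                if best is None or r.score < best.score:
                    best = r
    return best


def _downsample(vol: VoxelVolume, factor: int) -> VoxelVolume:
    from skimage.measure import block_reduce

    occ = block_reduce(vol.occupancy, (factor,) * 3, np.max)
    return VoxelVolume(occ, vol.spacing * factor,
                       vol.origin + (factor - 1) / 2.0 * vol.spacing)


def _plateau_center(objective, params: np.ndarray, axis: int,
                    step: float, span: float) -> np.ndarray:
    """Midpoint of the contiguous constant-score run through ``params`` along
    one parameter axis (the objective is a ratio of integer counts, so exact
    score equality is meaningful)."""
    base = objective(params)
    n = max(1, int(round(span / step)))

    def run_extent(sign: int) -> int:
        k = 0
        for i in range(1, n + 1):
            trial = params.copy()
            trial[axis] += sign * i * step
            if objective(trial) > base + 1e-15:
                break
            k = i
        return k

    hi, lo = run_extent(+1), run_extent(-1)
    out = params.copy()
    out[axis] += (hi - lo) / 2.0 * step
    return out


def find_osp(vol: VoxelVolume, config: OspConfig | None = None) -> SymmetryResult:
    """Locate the OSP starting from the mid-grid x-normal plane.

    The returned score is never worse than the initial-guess score (the best
    evaluation ever seen is returned).  The plane is sign-canonicalized.
    """
    config = config or OspConfig()
    vol.require_nonempty()

    levels = [4, 2, 1] if config.multiresolution else [1]
    x0 = np.array([0.0, 0.0, float(vol.grid_center[0])])
    best_params, best_score = None, np.inf
    trace: list = []

    for li, factor in enumerate(levels):
        v = _downsample(vol, factor) if factor > 1 else vol
        if v.count == 0:
            continue

        centers = v.occupied_centers()
        origin, spacing, shape = v.origin, v.spacing, np.asarray(v.shape)
        occ = v.occupancy
        total = len(centers)

        state = {"params": None, "score": np.inf}

        def objective(params):
            plane = _plane_from_params(params)
            mirrored = plane.mirror(centers)
            idx = round_half_down((mirrored - origin) / spacing)
            inside = np.all((idx >= 0) & (idx < shape), axis=1)
            paired = int(occ[tuple(idx[inside].T)].sum())
            f = 1.0 - paired / total
            if f < state["score"]:
                state["params"], state["score"] = np.array(params), f
            if config.trace:
                trace.append((tuple(params), f))
            return f

        objective(x0)  # monotonicity anchor: initial guess always evaluated

        if config.coarse_scan and li == 0:
            step = np.radians(config.scan_step_deg)
            half = np.radians(config.scan_half_angle_deg)
            step_off = float(spacing.min())
            centroid = centers.mean(axis=0)
            for az in np.arange(-half, half + 1e-12, step):
                for el in np.arange(-half, half + 1e-12, step):
                    # centre offsets on the foreground centroid projection so
                    # the scan is invariant to how the grid was laid out
                    n = np.array([np.cos(el) * np.cos(az),
                                  np.cos(el) * np.sin(az), np.sin(el)])
                    d0 = float(n @ centroid)
                    for k in range(-config.scan_offset_steps, config.scan_offset_steps + 1):
                        objective((az, el, d0 + k * step_off))

        starts = [state["params"].copy()]
        d5 = np.radians(5.0)
        perturbs = [(d5, 0.0, 0.0), (-d5, 0.0, 0.0), (0.0, d5, 0.0), (0.0, -d5, 0.0),
                    (0.0, 0.0, spacing.min()), (0.0, 0.0, -spacing.min())]
        starts += [starts[0] + np.asarray(p) for p in perturbs[: config.restarts]]

        scale = np.array([np.radians(2.0), np.radians(2.0), 0.5 * spacing.min()])
        for s in starts:
            simplex = np.vstack([s, s + np.diag(scale)])
            optimize.minimize(
                objective, s, method="Nelder-Mead",
                options={"initial_simplex": simplex, "fatol": config.fatol,
                         "xatol": 1e-4, "maxfev": config.max_evals},
            )

        x0 = state["params"].copy()
        if factor == 1:
            # the objective is piecewise constant: centre each parameter on
            # its minimal-score plateau for an unbiased sub-voxel estimate
            params = state["params"].copy()
            steps = (np.radians(0.1), np.radians(0.1), float(spacing.min()) / 16.0)
            spans = (np.radians(2.0), np.radians(2.0), float(spacing.min()))
            for axis in (0, 1, 2):
                params = _plateau_center(objective, params, axis,
                                         steps[axis], spans[axis])
            best_params, best_score = params, objective(params)

    result = symmetry_score(vol, _plane_from_params(best_params))
    result.optimizer_trace = trace
    initial = symmetry_score(vol, _plane_from_params(
        (0.0, 0.0, float(vol.grid_center[0]))))
    result.warning = result.score >= initial.score and result.score > 0.0
    if initial.score < result.score:  # defensive: never worse than the guess
        initial.optimizer_trace = trace
        initial.warning = True
        return initial
    return result
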
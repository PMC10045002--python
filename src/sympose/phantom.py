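"""Synthetic vertebra-like voxel phantoms with known ground truth.

The phantom is the simplest solid with the bilateral topology the
symmetry-based superposition method exploits: an elliptic-cylinder vertebral
body (anterior), two pedicle cylinders, a transverse lamina bar and a spinous
box (posterior), all built as functions of ``|x - cx|`` so the emitted volume
is *exactly* mirror symmetric about the grid-aligned plane ``x = cx`` when no
asymmetry, deformation or artifacts are requested.

Axis convention (anatomical): x = left-right (symmetry-plane normal),
y = posterior -> anterior, z = inferior -> superior.  The posterior elements
sit at the low-y end, so a band of fractional width gamma measured from y_min
selects the spinous region.  The body is shifted 1 mm superior and the
posterior elements 1 mm inferior, which breaks the superior-inferior mirror
symmetry just enough for downstream axis-sign conventions to resolve
deterministically.

Controllable degradations, all seeded:

* ``asymmetry_amplitude`` — a band-limited random inflation/erosion field
  applied to one lateral half only (emulates natural bilateral asymmetry);
* ``lamina_removal_fraction`` — deletes the most posterior fraction of
  posterior-element voxels (emulates laminoplasty/laminectomy);
* ``artifact_blob_count`` / ``artifact_blob_radius_mm`` — high-intensity
  blobs unioned into the foreground near the pedicles (emulates metal-implant
  streak artifacts that survive segmentation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import PhantomFitError
from .geometry import Plane, RigidTransform
from .volume import VoxelVolume, round_half_down


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple = (64, 64, 64)
    spacing: tuple = (0.5, 0.5, 0.5)
    body_radii: tuple = (8.0, 6.0)      # (x, y) semi-axes of the body, mm
    body_height: float = 10.0           # superior-inferior extent of the body, mm
    pedicle_radius: float = 2.5         # mm
    pedicle_offset: float = 4.5         # lateral distance of pedicle axes, mm
    spinous_length: float = 8.0         # mm
    asymmetry_amplitude: float = 0.0    # mm, max |displacement| on one half
    lamina_removal_fraction: float = 0.0
    artifact_blob_count: int = 0
    artifact_blob_radius_mm: float = 1.5
    true_plane: Plane | None = None     # must be x-normal; None -> mid-grid
    seed: int = 0

    def validate(self) -> None:
        if any(int(n) < 16 for n in self.grid_shape):
            raise ValueError("grid_shape components must all be >= 16")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if not 0.0 <= self.lamina_removal_fraction <= 1.0:
            raise ValueError("lamina_removal_fraction must be in [0, 1]")
        if self.artifact_blob_count < 0 or self.artifact_blob_radius_mm <= 0:
            raise ValueError("invalid artifact parameters")
        if self.true_plane is not None and not np.allclose(
            self.true_plane.normal, (1.0, 0.0, 0.0), atol=1e-9
        ):
            raise ValueError("true_plane must be grid-aligned with normal (1,0,0)")


@dataclass
class Phantom:
    """A generated phantom plus its ground truth."""

    volume: VoxelVolume
    true_plane: Plane
    body_mask: np.ndarray       # anatomy: vertebral body voxels
    posterior_mask: np.ndarray  # anatomy: pedicles + lamina + spinous
    artifact_mask: np.ndarray   # implant-artifact voxels (outside the anatomy)
    spec: PhantomSpec
    applied_transform: RigidTransform = field(default_factory=RigidTransform.identity)

    @property
    def anatomy_mask(self) -> np.ndarray:
        return self.body_mask | self.posterior_mask

    def body_points(self) -> np.ndarray:
        return self.volume.index_to_world(np.argwhere(self.body_mask))

    def write_ground_truth(self, path) -> Path:
        """Sidecar JSON with the true plane, applied transform and component
        voxel-index lists."""
        path = Path(path)
        path.write_text(json.dumps({
            "true_plane": self.true_plane.to_dict(),
            "applied_transform": self.applied_transform.to_dict(),
            "seed": self.spec.seed,
            "spacing": self.volume.spacing.tolist(),
            "origin": self.volume.origin.tolist(),
            "body_voxels": np.argwhere(self.body_mask).tolist(),
            "posterior_voxels": np.argwhere(self.posterior_mask).tolist(),
            "artifact_voxels": np.argwhere(self.artifact_mask).tolist(),
        }, sort_keys=True))
        return path


def make_phantom(spec: PhantomSpec) -> Phantom:
    spec.validate()
    nx, ny, nz = (int(n) for n in spec.grid_shape)
    sp = np.asarray(spec.spacing, dtype=float)
    x = np.arange(nx)[:, None, None] * sp[0]
    y = np.arange(ny)[None, :, None] * sp[1]
    z = np.arange(nz)[None, None, :] * sp[2]

    cx = (nx - 1) / 2.0 * sp[0] if spec.true_plane is None else spec.true_plane.offset
    cz = (nz - 1) / 2.0 * sp[2]
    ly = (ny - 1) * sp[1]
    rx, ry = spec.body_radii
    cy_body = ly - 4.0 - ry
    cz_body = cz + 1.0       # superior shift (breaks z mirror symmetry)
    cz_post = cz - 1.0
    lam_y0 = cy_body - ry - 3.0
    lam_y1 = cy_body - ry + 1.0
    spin_y0 = lam_y0 - spec.spinous_length

    margin = 1.5 * float(sp.max())
    if spin_y0 < margin:
        raise PhantomFitError("phantom does not fit grid: spinous process leaves the domain")
    if cx - rx < margin or cx + rx > (nx - 1) * sp[0] - margin:
        raise PhantomFitError("phantom does not fit grid: body too wide for the grid")
    if cz_body + spec.body_height / 2.0 + 3.5 > (nz - 1) * sp[2] - margin or \
            cz_post - spec.pedicle_radius < margin:
        raise PhantomFitError("phantom does not fit grid: body too tall for the grid")

    ax = np.abs(x - cx)  # symmetric coordinate: exact mirror symmetry by construction
    body = (((ax / rx) ** 2 + ((y - cy_body) / ry) ** 2) <= 1.0) \
        & (np.abs(z - cz_body) <= spec.body_height / 2.0)
    # domed superior endplate: adds superior extent without moving the centroid
    # much, so the superior-inferior axis-sign convention resolves robustly
    body_top = cz_body + spec.body_height / 2.0
    body |= ((ax / rx) ** 2 + ((y - cy_body) / ry) ** 2
             + ((z - body_top) / 3.5) ** 2 <= 1.0) & (z > body_top)
    pedicles = (((ax - spec.pedicle_offset) ** 2 + (z - cz_post) ** 2)
                <= spec.pedicle_radius ** 2) & (y >= lam_y0) & (y <= cy_body)
    lamina = (ax <= spec.pedicle_offset + spec.pedicle_radius) \
        & (y >= lam_y0) & (y <= lam_y1) & (np.abs(z - cz_post) <= spec.pedicle_radius)
    # spinous process tapers to a posterior point over its full length: its
    # silhouette tip is a sharp (~35 deg) corner, the dominant turning-point
    # feature, as on a real (pointed) spinous process
    spin_halfwidth = np.minimum(2.5, 2.5 * (y - spin_y0) / max(spec.spinous_length, 1e-6))
    spinous = (ax <= 1.5) & (y >= spin_y0) & (y <= lam_y0 + 0.5) \
        & (np.abs(z - cz_post) <= spin_halfwidth)

    posterior = (pedicles | lamina | spinous) & ~body
    solid = body | posterior

    rng = np.random.default_rng(spec.seed)

    if spec.asymmetry_amplitude > 0:
        phi = ndimage.gaussian_filter(rng.standard_normal((ny, nz)), sigma=3.0)
        phi *= spec.asymmetry_amplitude / np.abs(phi).max()
        sd = ndimage.distance_transform_edt(~solid, sampling=sp) \
            - ndimage.distance_transform_edt(solid, sampling=sp)
        half = np.broadcast_to(x > cx, solid.shape)
        new = solid.copy()
        new[half] = (sd <= phi[None, :, :])[half]
        # reassign components of added/removed voxels by proximity
        dt_b = ndimage.distance_transform_edt(~body, sampling=sp)
        dt_p = ndimage.distance_transform_edt(~posterior, sampling=sp)
        body = new & (dt_b <= dt_p)
        posterior = new & ~body
        solid = new

    n_comp = ndimage.label(solid)[1]  # default structure = 6-connectivity
    if n_comp != 1:
        raise PhantomFitError(f"phantom is not a single 6-connected component ({n_comp})")

    if spec.lamina_removal_fraction > 0:
        # laminoplasty-like deformation: the lateral lamina/pedicle arch is
        # carved away first (most lateral voxels removed in descending |x-cx|
        # order), changing the 3D posterior morphology while largely
        # preserving the midline sagittal silhouette and the spinous tip
        idx = np.argwhere(posterior)
        lateral = np.abs(idx[:, 0] * sp[0] - cx)
        order = np.lexsort((idx[:, 2], idx[:, 0], idx[:, 1], -lateral))
        n_remove = int(round(spec.lamina_removal_fraction * len(idx)))
        removed = idx[order[:n_remove]]
        posterior[tuple(removed.T)] = False
        solid = body | posterior

    artifacts = np.zeros_like(solid)
    for blob in range(spec.artifact_blob_count):
        side = 1.0 if blob % 2 == 0 else -1.0  # implants are bilateral
        center = np.array([
            cx + side * spec.pedicle_offset + rng.normal(0.0, 2.0),
            lam_y0 + 2.0 + rng.normal(0.0, 3.0),
            cz_post + rng.normal(0.0, 2.0),
        ])
        blob = ((x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2) \
            <= spec.artifact_blob_radius_mm ** 2
        artifacts |= blob
    artifacts &= ~solid

    vol = VoxelVolume(solid | artifacts, sp, np.zeros(3))
    return Phantom(
        volume=vol,
        true_plane=Plane((1.0, 0.0, 0.0), cx),
        body_mask=body,
        posterior_mask=posterior,
        artifact_mask=artifacts,
        spec=spec,
    )


def transform_phantom(ph: Phantom, xf: RigidTransform) -> Phantom:
    """Rigidly move a phantom and resample it (nearest neighbor) onto a grid
    large enough to contain it; ground truth is carried along.

    If the moved object still fits the existing grid the grid is kept, so a
    grid-commensurate translation shifts occupied indices exactly.
    """
    vol = ph.volume
    sp, org = vol.spacing, vol.origin
    occ_idx = vol.occupied_indices()
    if len(occ_idx) == 0:
        return Phantom(vol.copy(), ph.true_plane.transformed(xf), ph.body_mask.copy(),
                       ph.posterior_mask.copy(), ph.artifact_mask.copy(), ph.spec,
                       xf @ ph.applied_transform)

    moved = xf.apply(vol.index_to_world(occ_idx))
    lo, hi = moved.min(axis=0), moved.max(axis=0)
    gmin, gmax = vol.world_bounds()
    if np.all(lo >= gmin - 0.5 * sp) and np.all(hi <= gmax + 0.5 * sp):
        new_origin, new_shape = org.copy(), vol.shape
    else:
        new_origin = org + sp * np.floor((np.minimum(lo, gmin) - org) / sp) - 2 * sp
        new_shape = tuple(
            (np.ceil((np.maximum(hi, gmax) - new_origin) / sp) + 3).astype(int)
        )

    idx_grid = np.indices(new_shape).reshape(3, -1).T
    centers = new_origin + idx_grid * sp
    back = xf.inverse().apply(centers)
    src = round_half_down((back - org) / sp)
    shape_arr = np.asarray(vol.shape)
    inside = np.all((src >= 0) & (src < shape_arr), axis=1)
    src_in = tuple(src[inside].T)
    dst_flat = np.flatnonzero(inside)

    def resample(mask: np.ndarray) -> np.ndarray:
        out = np.zeros(new_shape, dtype=bool)
        out.ravel()[dst_flat] = mask[src_in]
        return out

    new_vol = VoxelVolume(resample(vol.occupancy), sp, new_origin)
    return Phantom(
        volume=new_vol,
        true_plane=ph.true_plane.transformed(xf),
        body_mask=resample(ph.body_mask),
        posterior_mask=resample(ph.posterior_mask),
        artifact_mask=resample(ph.artifact_mask),
        spec=ph.spec,
        applied_transform=xf @ ph.applied_transform,
    )


def make_phantom_pair(
    seed: int,
    *,
    grid_shape=(48, 48, 48),
    spacing=(0.7, 0.7, 0.7),
    asymmetry_amplitude: float = 0.5,
    lamina_removal_fraction: float = 0.25,
    artifact_blob_count: int = 8,
    artifact_blob_radius_mm: float = 2.5,
    max_rotation_deg: float = 8.0,
    max_translation_mm: float = 4.0,
) -> tuple[Phantom, Phantom, RigidTransform]:
    """A pre/post study pair: the intact phantom, a deformed + artifact-laden
    copy moved by a random rigid transform, and that ground-truth transform.

    The deformed phantom shares the pre phantom's seed, hence its asymmetry
    field: the pair differs only by surgery-like degradation plus pose.  The
    default artifact load (8 blobs of 2.5 mm radius) puts roughly a tenth of
    the foreground into implant artifacts, the volume ratio at which metal
    implants are known to derail closest-point registration.
    """
    base = PhantomSpec(grid_shape=grid_shape, spacing=spacing,
                       asymmetry_amplitude=asymmetry_amplitude, seed=seed)
    pre = make_phantom(base)
    post_spec = replace(base, lamina_removal_fraction=lamina_removal_fraction,
                        artifact_blob_count=artifact_blob_count,
                        artifact_blob_radius_mm=artifact_blob_radius_mm)
    post0 = make_phantom(post_spec)

    rng = np.random.default_rng(seed + 10_000)
    axis = rng.standard_normal(3)
    angle = rng.uniform(0.3, 1.0) * max_rotation_deg
    t = rng.uniform(-1.0, 1.0, 3) * max_translation_mm
    xf = RigidTransform.from_translation(t) @ RigidTransform.from_axis_angle(
        axis, angle, center=post0.volume.grid_center)
    post = transform_phantom(post0, xf)
    return pre, post, xf
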
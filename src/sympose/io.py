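"""Reading and writing volumes, meshes, and the pipeline's JSON artifacts.

Supported volume formats: NRRD (``.nrrd``), NIfTI (``.nii``/``.nii.gz``) and a
plain raw-array + JSON-metadata fallback (``.json`` + sibling ``.raw``).  All
volume I/O is lossless for binary content.  STL is read and written in both
binary and ASCII flavors; vertices are deduplicated by exact coordinate match
on read so the vertex point cloud has unique points.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np

from .errors import EmptyVolumeError, UnreadableMeshError, UnreadableVolumeError
from .geometry import Plane, PlaneFrame, RigidTransform
from .mesh import TriangleMesh
from .volume import VoxelVolume

_FORMATS = ("nrrd", "nifti", "rawmeta")


def _infer_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nrrd"):
        return "nrrd"
    if name.endswith(".nii") or name.endswith(".nii.gz"):
        return "nifti"
    if name.endswith(".json"):
        return "rawmeta"
    raise UnreadableVolumeError(f"unreadable volume: unknown format for {path}")


def read_volume(path, format: str | None = None, threshold: float | str = "nonzero") -> VoxelVolume:
    """Read a volume; any voxel passing ``threshold`` becomes occupied.

    ``threshold="nonzero"`` (default) marks every nonzero label occupied;
    a numeric threshold marks values ``>= threshold``.
    """
    path = Path(path)
    if not path.exists():
        raise UnreadableVolumeError(f"unreadable volume: {path} does not exist")
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise UnreadableVolumeError(f"unreadable volume: unknown format {fmt!r}")
    try:
        if fmt == "nrrd":
            arr, spacing, origin = _read_sitk(path)
        elif fmt == "nifti":
            arr, spacing, origin = _read_nifti(path)
        else:
            arr, spacing, origin = _read_rawmeta(path)
    except UnreadableVolumeError:
        raise
    except Exception as exc:  # noqa: BLE001 - normalize backend failures
        raise UnreadableVolumeError(f"unreadable volume: {path}: {exc}") from exc
    if np.any(np.asarray(spacing) <= 0):
        raise UnreadableVolumeError("unreadable volume: non-positive spacing metadata")
    occ = (arr != 0) if threshold == "nonzero" else (arr >= float(threshold))
    return VoxelVolume(occ, spacing, origin)


def write_volume(vol: VoxelVolume, path, format: str | None = None) -> Path:
    """Write a binary volume; raises on empty input."""
    if vol.count == 0:
        raise EmptyVolumeError("empty volume")
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "nrrd":
        _write_sitk(vol, path)
    elif fmt == "nifti":
        _write_nifti(vol, path)
    elif fmt == "rawmeta":
        _write_rawmeta(vol, path)
    else:
        raise UnreadableVolumeError(f"unreadable volume: unknown format {fmt!r}")
    return path


# -- NRRD via SimpleITK ----------------------------------------------------

def _read_sitk(path: Path):
    import SimpleITK as sitk

    img = sitk.ReadImage(os.fspath(path))
    if not np.allclose(np.asarray(img.GetDirection()).reshape(3, 3), np.eye(3), atol=1e-6):
        raise UnreadableVolumeError("unreadable volume: non-identity direction matrix")
    # SimpleITK arrays come back (z, y, x); transpose to our (x, y, z).
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return arr, np.asarray(img.GetSpacing()), np.asarray(img.GetOrigin())


def _write_sitk(vol: VoxelVolume, path: Path) -> None:
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(vol.occupancy.astype(np.uint8).transpose(2, 1, 0))
    img.SetSpacing(tuple(vol.spacing))
    img.SetOrigin(tuple(vol.origin))
    sitk.WriteImage(img, os.fspath(path))


# -- NIfTI via nibabel -----------------------------------------------------

def _read_nifti(path: Path):
    import nibabel as nib

    img = nib.load(os.fspath(path))
    affine = img.affine
    rot = affine[:3, :3]
    if not np.allclose(rot - np.diag(np.diag(rot)), 0.0, atol=1e-6):
        raise UnreadableVolumeError("unreadable volume: non-axis-aligned NIfTI affine")
    spacing = np.diag(rot)
    if np.any(spacing <= 0):
        raise UnreadableVolumeError("unreadable volume: non-positive spacing metadata")
    return np.asanyarray(img.dataobj), spacing, affine[:3, 3]


def _write_nifti(vol: VoxelVolume, path: Path) -> None:
    import nibabel as nib

    affine = np.eye(4)
    affine[:3, :3] = np.diag(vol.spacing)
    affine[:3, 3] = vol.origin
    nib.save(nib.Nifti1Image(vol.occupancy.astype(np.uint8), affine), os.fspath(path))


# -- raw + JSON metadata fallback -----------------------------------------

def _read_rawmeta(path: Path):
    meta = json.loads(path.read_text())
    required = {"shape", "spacing", "origin", "dtype", "data_file"}
    if not required.issubset(meta):
        raise UnreadableVolumeError("unreadable volume: missing metadata keys")
    raw = path.parent / meta["data_file"]
    arr = np.fromfile(raw, dtype=np.dtype(meta["dtype"])).reshape(meta["shape"])
    return arr, np.asarray(meta["spacing"], dtype=float), np.asarray(meta["origin"], dtype=float)


def _write_rawmeta(vol: VoxelVolume, path: Path) -> None:
    raw_name = path.with_suffix(".raw").name
    vol.occupancy.astype(np.uint8).tofile(path.parent / raw_name)
    path.write_text(json.dumps({
        "shape": list(vol.shape),
        "spacing": vol.spacing.tolist(),
        "origin": vol.origin.tolist(),
        "dtype": "uint8",
        "data_file": raw_name,
    }, indent=2))


# -- STL -------------------------------------------------------------------

def read_stl(path) -> TriangleMesh:
    """Read STL (binary or ASCII); vertices deduplicated by exact match."""
    import trimesh

    path = Path(path)
    if not path.exists():
        raise UnreadableMeshError(f"unreadable mesh: {path} does not exist")
    try:
        tm = trimesh.load_mesh(os.fspath(path), file_type="stl", process=False)
        soup = tm.vertices[tm.faces]
    except Exception as exc:  # noqa: BLE001
        raise UnreadableMeshError(f"unreadable mesh: {path}: {exc}") from exc
    mesh = TriangleMesh.from_triangle_soup(soup)
    if len(mesh.faces) == 0:
        raise UnreadableMeshError("unreadable mesh: no non-degenerate facets")
    return mesh


def write_stl(mesh: TriangleMesh, path, mode: str = "binary") -> Path:
    import trimesh

    if mode not in ("binary", "ascii"):
        raise ValueError("mode must be 'binary' or 'ascii'")
    path = Path(path)
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    data = trimesh.exchange.stl.export_stl_ascii(tm) if mode == "ascii" \
        else trimesh.exchange.stl.export_stl(tm)
    if isinstance(data, str):
        path.write_text(data)
    else:
        path.write_bytes(data)
    return path


# -- JSON artifacts --------------------------------------------------------

_TAGGED = {"plane": Plane, "rigid_transform": RigidTransform, "plane_frame": PlaneFrame}


def save_json(obj, path, **extra) -> Path:
    """Serialize a Plane / RigidTransform / PlaneFrame (plus extras) to JSON."""
    path = Path(path)
    for tag, cls in _TAGGED.items():
        if isinstance(obj, cls):
            payload = {"type": tag, **obj.to_dict(), **extra}
            break
    else:
        payload = obj
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path


def load_json(path):
    d = json.loads(Path(path).read_text())
    if isinstance(d, dict) and d.get("type") in _TAGGED:
        return _TAGGED[d["type"]].from_dict(d)
    return d
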
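"""CT volume I/O, coordinate transforms, and surface-mesh export.

The internal world frame is the DICOM patient frame (LPS: +x left, +y
posterior, +z superior), in millimetres.  Voxel indices are 0-based and an
integer index addresses the voxel centre.  NIfTI input (whose affine maps to
RAS) is converted to LPS on load and back on save, so a save/load round trip
is the identity.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import nibabel as nib
import pydicom

__all__ = [
    "CTVolume",
    "TriMesh",
    "load_volume",
    "save_nifti",
    "world_from_voxel",
    "voxel_from_world",
    "extract_surface",
    "write_obj",
    "read_obj",
]

#: LPS <-> RAS conversion (its own inverse).
_LPS_FROM_RAS = np.diag([-1.0, -1.0, 1.0, 1.0])

SUPERIOR = np.array([0.0, 0.0, 1.0])
ANTERIOR = np.array([0.0, -1.0, 0.0])


@dataclass
class CTVolume:
    """A 3-D scalar grid in Hounsfield units with a voxel->world affine.

    Attributes
    ----------
    voxels : ndarray
        3-D array of HU values.
    affine : ndarray, shape (4, 4)
        Maps homogeneous continuous voxel indices to world mm (LPS).
    orientation_tag : str
        Anatomical axis codes of the world frame; always ``"LPS"`` here.
    """

    voxels: np.ndarray
    affine: np.ndarray
    orientation_tag: str = "LPS"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got shape {self.voxels.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine is singular")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("HU values must be finite")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing components must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm (column norms of the linear part)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)


@dataclass
class TriMesh:
    """Triangle mesh in world mm with 0-based face indices."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=int).reshape(-1, 3)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")
        if self.faces.size:
            a, b, c = self.faces.T
            if np.any((a == b) | (b == c) | (a == c)):
                raise ValueError("degenerate (repeated-vertex) triangle")


# ---------------------------------------------------------------------------
# coordinate transforms


def world_from_voxel(vol: CTVolume, ijk) -> np.ndarray:
    """Map continuous voxel indices (…, 3) to world mm."""
    ijk = np.asarray(ijk, dtype=float)
    return ijk @ vol.affine[:3, :3].T + vol.affine[:3, 3]


def voxel_from_world(vol: CTVolume, xyz) -> np.ndarray:
    """Map world mm points (…, 3) to continuous voxel indices."""
    inv = np.linalg.inv(vol.affine)
    xyz = np.asarray(xyz, dtype=float)
    return xyz @ inv[:3, :3].T + inv[:3, 3]


# ---------------------------------------------------------------------------
# loading


def load_volume(path, format_hint: str = "auto") -> CTVolume:
    """Load a CT volume from a NIfTI file or a DICOM series directory.

    Parameters
    ----------
    path : str or Path
        NIfTI file or directory containing one DICOM series.
    format_hint : {"auto", "nifti", "dicom_dir"}
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format_hint == "auto":
        format_hint = "dicom_dir" if path.is_dir() else "nifti"
    if format_hint == "nifti":
        return _load_nifti(path)
    if format_hint == "dicom_dir":
        return _load_dicom_dir(path)
    raise ValueError(f"unknown format hint {format_hint!r}")


def _load_nifti(path: Path) -> CTVolume:
    img = nib.load(str(path))
    voxels = np.asarray(img.dataobj).astype(np.float32)
    affine = _LPS_FROM_RAS @ img.affine
    return CTVolume(voxels=voxels, affine=affine)


def save_nifti(vol_or_mask, path, affine: np.ndarray | None = None) -> None:
    """Write a :class:`CTVolume` (or a raw array plus affine) as NIfTI-1."""
    if isinstance(vol_or_mask, CTVolume):
        data, aff = vol_or_mask.voxels, vol_or_mask.affine
    else:
        if affine is None:
            raise ValueError("affine required when saving a raw array")
        data, aff = np.asarray(vol_or_mask), affine
    if data.dtype == bool:
        data = data.astype(np.uint8)
    ras_affine = _LPS_FROM_RAS @ np.asarray(aff, dtype=float)
    img = nib.Nifti1Image(data, ras_affine)
    nib.save(img, str(path))


def _load_dicom_dir(path: Path) -> CTVolume:
    files = sorted(p for p in path.iterdir() if p.is_file())
    datasets = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            datasets.append(ds)
    if not datasets:
        raise ValueError(f"no DICOM images found in {path}")

    uids = {str(getattr(ds, "SeriesInstanceUID", "?")) for ds in datasets}
    if len(uids) > 1:
        raise ValueError(f"mixed DICOM series: {sorted(uids)}")
    for ds in datasets:
        if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
            raise ValueError("missing RescaleSlope/RescaleIntercept tags")

    iop = np.array(datasets[0].ImageOrientationPatient, dtype=float)
    row_dir, col_dir = iop[:3], iop[3:]  # row_dir: along increasing column index
    normal = np.cross(row_dir, col_dir)

    # sort by ImagePositionPatient projected on the slice normal
    datasets.sort(key=lambda ds: float(np.dot(np.array(ds.ImagePositionPatient, float), normal)))

    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float32)
        slices.append(arr * float(ds.RescaleSlope) + float(ds.RescaleIntercept))
    vol = np.stack(slices, axis=0)  # (slice, row, col)

    ps = np.array(datasets[0].PixelSpacing, dtype=float)  # (row spacing, col spacing)
    origin = np.array(datasets[0].ImagePositionPatient, dtype=float)
    if len(datasets) > 1:
        last = np.array(datasets[-1].ImagePositionPatient, dtype=float)
        dz = float(np.dot(last - origin, normal)) / (len(datasets) - 1)
    else:
        dz = float(getattr(datasets[0], "SliceThickness", 1.0) or 1.0)

    affine = np.eye(4)
    affine[:3, 0] = normal * dz       # slice index
    affine[:3, 1] = col_dir * ps[0]   # row index
    affine[:3, 2] = row_dir * ps[1]   # column index
    affine[:3, 3] = origin
    return CTVolume(voxels=vol, affine=affine)


# ---------------------------------------------------------------------------
# surface extraction and OBJ


def extract_surface(mask: np.ndarray, affine: np.ndarray) -> TriMesh:
    """Extract the closed iso-0.5 boundary surface of a binary mask.

    Vertices are returned in world mm.  The mask is padded by one background
    voxel so the surface closes even when the mask touches the grid border.
    """
    from skimage import measure

    mask = np.asarray(mask)
    if not mask.any():
        raise ValueError("mask is empty")
    padded = np.pad(mask.astype(np.float32), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5)
    verts = verts - 1.0  # undo padding offset; still in voxel-index space
    affine = np.asarray(affine, dtype=float)
    world = verts @ affine[:3, :3].T + affine[:3, 3]
    # drop any degenerate faces the mesher may emit
    a, b, c = faces.T
    keep = (a != b) & (b != c) & (a != c)
    return TriMesh(vertices=world, faces=faces[keep])


def write_obj(mesh: TriMesh, path) -> None:
    """Write a Wavefront OBJ (ASCII, 1-based face indices)."""
    if mesh.faces.size == 0:
        raise ValueError("mesh has no faces")
    lines = []
    for v in mesh.vertices:
        lines.append(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}")
    for f in mesh.faces:
        lines.append(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_obj(path) -> TriMesh:
    """Parse an ASCII OBJ written by :func:`write_obj`."""
    verts, faces = [], []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "v":
            verts.append([float(x) for x in parts[1:4]])
        elif parts[0] == "f":
            faces.append([int(p.split("/")[0]) - 1 for p in parts[1:4]])
    return TriMesh(vertices=np.array(verts, dtype=float),
                   faces=np.array(faces, dtype=int).reshape(-1, 3))
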
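"""Volume, label-map, mesh and report I/O.

All images live in NIfTI-1 files with an RAS+ affine; voxel indices are
0-based, world coordinates are millimetres, volumes are reported in mL
(mm^3 / 1000).  Label maps are stored as uint8 with 0 reserved for
"unlabeled" (seed maps) and codes 1..4 for background, blood pool,
myocardium and scar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

from .errors import EmptySurfaceError, FormatError, GridMismatchError

#: canonical tissue codes used throughout the package
TISSUE_CODES: dict[int, str] = {1: "background", 2: "blood", 3: "myocardium", 4: "scar"}

#: inverse map, name -> code
TISSUE_NAMES: dict[str, int] = {v: k for k, v in TISSUE_CODES.items()}


def _affine_from_spacing(spacing_mm: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_mm
    return aff


@dataclass
class Volume3D:
    """A 3D scalar image with voxel spacing (mm) and a voxel->world affine."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    affine: np.ndarray = None  # type: ignore[assignment]
    units: str = "a.u."

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(f"Volume3D requires a 3D array, got ndim={self.data.ndim}")
        if np.isscalar(self.spacing_mm) or np.ndim(self.spacing_mm) == 0:
            self.spacing_mm = (float(self.spacing_mm),) * 3
        else:
            self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or min(self.spacing_mm) <= 0:
            raise FormatError(f"spacing must be 3 positive values, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("volume contains non-finite voxels")
        if self.affine is None:
            self.affine = _affine_from_spacing(self.spacing_mm)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise FormatError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def is_isotropic(self) -> bool:
        s = self.spacing_mm
        return max(s) / min(s) <= 1.01

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


@dataclass
class LabelMap:
    """Integer-coded voxel labels on the same grid as a companion volume.

    ``0`` means unlabeled (legal in seed maps); all other values must be
    listed in ``codes``.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    affine: np.ndarray = None  # type: ignore[assignment]
    codes: Mapping[int, str] = field(default_factory=lambda: dict(TISSUE_CODES))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(f"LabelMap requires a 3D array, got ndim={self.data.ndim}")
        if not np.issubdtype(self.data.dtype, np.integer):
            rounded = np.rint(self.data)
            if not np.array_equal(rounded, self.data):
                raise FormatError("label map has non-integer values")
            self.data = rounded.astype(np.uint8)
        if np.isscalar(self.spacing_mm) or np.ndim(self.spacing_mm) == 0:
            self.spacing_mm = (float(self.spacing_mm),) * 3
        else:
            self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if self.affine is None:
            self.affine = _affine_from_spacing(self.spacing_mm)
        self.affine = np.asarray(self.affine, dtype=float)
        self.codes = dict(self.codes)
        allowed = {0} | set(self.codes)
        present = set(np.unique(self.data).tolist())
        if not present <= allowed:
            raise FormatError(f"labels {sorted(present - allowed)} outside declared codes {sorted(allowed)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def mask(self, code: int) -> np.ndarray:
        return self.data == code

    def same_grid(self, other) -> bool:
        return self.shape == other.shape and np.allclose(self.spacing_mm, other.spacing_mm)


def check_same_grid(a, b, what: str = "inputs") -> None:
    if a.data.shape != b.data.shape or not np.allclose(a.spacing_mm, b.spacing_mm):
        raise GridMismatchError(
            f"{what} are on different grids: {a.data.shape}@{a.spacing_mm} vs {b.data.shape}@{b.spacing_mm}"
        )


# ---------------------------------------------------------------------------
# NIfTI volumes
# ---------------------------------------------------------------------------

def read_volume(path: str | Path) -> Volume3D:
    """Read a NIfTI-1 scalar volume.

    Raises :class:`FormatError` for missing files, non-3D payloads and
    non-finite voxel values.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path.name}: expected a 3D volume, got {data.ndim}D payload")
    data = np.asarray(data, dtype=np.float32)
    if not np.all(np.isfinite(data)):
        raise FormatError(f"{path.name}: volume contains non-finite voxels")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume3D(data=data, spacing_mm=spacing, affine=np.asarray(img.affine))


def write_volume(vol: Volume3D, path: str | Path) -> Path:
    """Write a :class:`Volume3D` as float32 NIfTI-1 (lossless round trip at float32)."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), vol.affine)
    img.header.set_zooms(vol.spacing_mm)
    nib.save(img, str(path))
    return path


def read_labels(path: str | Path, codes: Mapping[int, str] | None = None) -> LabelMap:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path.name}: expected a 3D label map, got {data.ndim}D payload")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if codes is None:
        present = set(int(v) for v in np.unique(data)) - {0}
        codes = {c: TISSUE_CODES.get(c, f"class_{c}") for c in present} or dict(TISSUE_CODES)
    return LabelMap(data=np.asarray(data).astype(np.uint8), spacing_mm=spacing,
                    affine=np.asarray(img.affine), codes=codes)


def write_labels(labels: LabelMap, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(labels.data, dtype=np.uint8), labels.affine)
    img.header.set_zooms(labels.spacing_mm)
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# Meshes
# ---------------------------------------------------------------------------

def write_mesh(vertices: np.ndarray, faces: np.ndarray, path: str | Path) -> Path:
    """Write a triangle mesh (world-mm vertices) as binary STL."""
    import trimesh

    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=int)
    if vertices.size == 0 or faces.size == 0:
        raise EmptySurfaceError("refusing to write an empty mesh")
    mesh = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    path = Path(path)
    mesh.export(str(path), file_type="stl")
    return path


def mask_to_mesh(mask: np.ndarray, spacing_mm, affine: np.ndarray | None = None):
    """Triangulate the 0.5 isosurface of a binary mask in world mm.

    Returns ``(vertices, faces)``.  The surface is the 0.5 level set of the
    sampled indicator within the grid: a mask touching the array border
    yields an open surface there rather than an artificial closing cap
    (which would distort surface-distance statistics).
    """
    from skimage import measure

    mask = np.asarray(mask)
    if not mask.any():
        raise EmptySurfaceError("cannot extract a surface from an empty mask")
    spacing = tuple(float(s) for s in np.broadcast_to(spacing_mm, (3,)))
    verts, faces, _, _ = measure.marching_cubes(mask.astype(np.float32), level=0.5,
                                                spacing=spacing)
    if affine is not None:
        # marching_cubes already applied spacing; go back to voxel indices,
        # then through the full affine (handles rotation + translation)
        hom = np.c_[verts / spacing, np.ones(len(verts))]
        verts = (np.asarray(affine) @ hom.T).T[:, :3]
    return verts, faces


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def write_report(report, path_json: str | Path, path_csv: str | Path) -> None:
    """Serialize an agreement report to JSON (nested) and CSV (one row/case).

    ``report`` must provide ``to_dict()`` and ``to_frame()``; see
    :class:`scarflow.metrics.AgreementReport`.
    """
    path_json = Path(path_json)
    path_csv = Path(path_csv)
    with open(path_json, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
    report.to_frame().to_csv(path_csv, index=False)


def read_report(path_json: str | Path):
    from .metrics import AgreementReport

    with open(path_json) as fh:
        payload = json.load(fh)
    return AgreementReport.from_dict(payload)
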
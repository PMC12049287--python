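"""Volume and mesh I/O, domain containers, run configuration.

Anatomical frame
----------------
Everything in this package lives in one right-handed, mm-unit world frame:

* ``+x`` points **medial** (ML axis),
* ``+y`` points **anterior** (AP axis),
* ``+z`` points **proximal** (PD axis).

A :class:`VolumeImage` stores which anatomical axis each array axis runs
along (``axes``); voxel index ``(i, j, k)`` maps to
``origin + (i*s0, j*s1, k*s2)`` distributed onto the labelled world axes,
indices 0-based, positive index direction = positive anatomical direction.
The labelling round-trips through the image direction-cosine matrix of
NIfTI / MetaImage files, so no private header fields are needed.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import SimpleITK as sitk
import trimesh
import yaml

from .errors import FormatError, GeometryError, ValidationError

log = logging.getLogger("resectfit")

#: Anatomical axis labels in canonical world order (x, y, z).
AXIS_LABELS = ("ML", "AP", "PD")
CANONICAL_AXES = AXIS_LABELS

_VOLUME_SUFFIXES = (".nii", ".nii.gz", ".mha", ".mhd")
_MESH_SUFFIXES = (".stl", ".ply", ".obj")


def setup_logging(level: int = logging.INFO) -> None:
    """Route package logs to stderr with levels (idempotent)."""
    if not log.handlers:
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        log.addHandler(h)
    log.setLevel(level)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class VolumeImage:
    """3D grey-value grid with per-axis spacing (mm) and anatomical labels."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = None  # type: ignore[assignment]
    axes: tuple[str, str, str] = CANONICAL_AXES

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 2:
            raise ValidationError("volume must be 3D with every axis >= 2")
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValidationError("spacing must be three positive components")
        if self.origin is None:
            self.origin = np.zeros(3)
        self.origin = np.asarray(self.origin, dtype=float)
        self.axes = tuple(self.axes)  # type: ignore[assignment]
        if sorted(self.axes) != sorted(AXIS_LABELS):
            raise ValidationError(
                f"axes must be a permutation of {AXIS_LABELS}, got {self.axes}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def axis_of(self, label: str) -> int:
        """Array axis running along anatomical direction *label*."""
        return self.axes.index(label)

    def world_permutation(self) -> np.ndarray:
        """3x3 permutation matrix P with column j = world direction of array axis j."""
        P = np.zeros((3, 3))
        for j, lab in enumerate(self.axes):
            P[AXIS_LABELS.index(lab), j] = 1.0
        return P

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map fractional voxel indices (N,3) to world mm coordinates."""
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return self.origin + (idx * self.spacing) @ self.world_permutation().T

    def copy(self) -> "VolumeImage":
        return replace(self, data=self.data.copy(), spacing=self.spacing.copy(),
                       origin=self.origin.copy())


@dataclass
class TriangleMesh:
    """Triangle surface: vertices in mm and vertex-index triples."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces):
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise ValidationError("face index out of range")
            a, b, c = self.faces.T
            if np.any((a == b) | (b == c) | (a == c)):
                raise ValidationError("degenerate face (repeated vertex index)")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh) -> "TriangleMesh":
        return cls(np.asarray(tm.vertices, dtype=float), np.asarray(tm.faces))

    def is_closed(self) -> bool:
        """Every edge shared by exactly two faces."""
        return bool(self.to_trimesh().is_watertight)


@dataclass
class PipelineConfig:
    """Declarative run configuration (YAML key/value file).

    Defaults mirror the documented pipeline defaults; every numeric knob is
    recorded in the per-run log for reproducibility.
    """

    threshold_mode: str = "otsu"                # {"fixed", "otsu"}
    fixed_threshold: Optional[float] = None
    crop_box: Optional[Sequence[Sequence[int]]] = None  # [[lo0,lo1,lo2],[hi0,hi1,hi2]]
    smoothing: bool = False
    smoothing_iterations: int = 10
    smoothing_relaxation: float = 0.1
    icp_max_iterations: int = 100
    icp_convergence_tol: float = 1e-6
    icp_trim_fraction: float = 0.1
    distance_unit: str = "voxel"                # {"voxel", "mm"}
    compartment_split_ap: float = 0.5
    compartment_split_ml: float = 0.5
    sclerosis_cutoff_fraction: float = 2.0 / 3.0
    sclerosis_cutoff_mode: str = "range"        # {"range", "quantile"}
    sclerosis_separation_guard: float = 11.0    # 0 disables the guard
    slice_min_area_fraction: float = 0.5
    mesh_scale: float = 1.0                     # STL unit fix-up if not mm
    render: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.threshold_mode not in ("fixed", "otsu"):
            raise ValidationError("threshold_mode must be 'fixed' or 'otsu'")
        if self.threshold_mode == "fixed" and self.fixed_threshold is None:
            raise ValidationError("fixed threshold_mode requires fixed_threshold")
        if self.distance_unit not in ("voxel", "mm"):
            raise ValidationError("distance_unit must be 'voxel' or 'mm'")
        for name in ("compartment_split_ap", "compartment_split_ml",
                     "sclerosis_cutoff_fraction", "slice_min_area_fraction"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0) and name != "slice_min_area_fraction":
                raise ValidationError(f"{name} must lie in (0, 1)")
        if not (0.0 < self.slice_min_area_fraction <= 1.0):
            raise ValidationError("slice_min_area_fraction must lie in (0, 1]")
        if self.icp_max_iterations < 1:
            raise ValidationError("icp_max_iterations must be >= 1")
        if not (0.0 <= self.icp_trim_fraction < 0.5):
            raise ValidationError("icp_trim_fraction must lie in [0, 0.5)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise FormatError(f"config {path} is not a key/value mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        if d["crop_box"] is not None:
            d["crop_box"] = [list(map(int, b)) for b in d["crop_box"]]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Volume I/O (SimpleITK; pydicom for the series-uniformity check)
# ---------------------------------------------------------------------------

def _axes_from_direction(direction: np.ndarray):
    """Decode a direction-cosine matrix into (labels, signs) per index axis.

    Only near-axis-aligned orientations are supported: each column must be
    within ~5 degrees of a signed world axis.
    """
    labels, signs = [], []
    for j in range(3):
        col = direction[:, j]
        k = int(np.argmax(np.abs(col)))
        if abs(col[k]) < 0.996:
            raise GeometryError("oblique image orientation is not supported")
        labels.append(AXIS_LABELS[k])
        signs.append(1.0 if col[k] > 0 else -1.0)
    if sorted(labels) != sorted(AXIS_LABELS):
        raise GeometryError("direction matrix is not a signed permutation")
    return labels, signs


def _from_sitk(img: sitk.Image) -> VolumeImage:
    arr = sitk.GetArrayFromImage(img)           # (k, j, i)
    arr = np.ascontiguousarray(arr.transpose(2, 1, 0))
    spacing = np.asarray(img.GetSpacing(), dtype=float)
    origin = np.asarray(img.GetOrigin(), dtype=float)
    direction = np.asarray(img.GetDirection(), dtype=float).reshape(3, 3)
    labels, signs = _axes_from_direction(direction)
    # Flip axes stored in the negative anatomical direction so the in-memory
    # convention is always "index increases along +axis".
    for j in range(3):
        if signs[j] < 0:
            arr = np.flip(arr, axis=j)
            origin = origin + direction[:, j] * spacing[j] * (arr.shape[j] - 1)
    # origin is in world (x,y,z) = (ML,AP,PD) order already.
    return VolumeImage(np.ascontiguousarray(arr), spacing, origin, tuple(labels))


def _to_sitk(vol: VolumeImage) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    img.SetDirection(tuple(vol.world_permutation().ravel()))
    return img


def _read_dicom_series(path: Path) -> VolumeImage:
    import pydicom

    reader = sitk.ImageSeriesReader()
    names = reader.GetGDCMSeriesFileNames(str(path))
    if not names:
        raise FormatError(f"no DICOM series found in {path}")
    # Uniform-slice-spacing check from the headers (ordering by slice
    # position, never by file name).
    positions = []
    for fn in names:
        ds = pydicom.dcmread(fn, stop_before_pixels=True)
        ori = np.asarray(getattr(ds, "ImageOrientationPatient",
                                 [1, 0, 0, 0, 1, 0]), dtype=float)
        normal = np.cross(ori[:3], ori[3:])
        positions.append(float(np.dot(np.asarray(ds.ImagePositionPatient, float),
                                      normal)))
    positions = np.sort(np.asarray(positions))
    if len(positions) > 2:
        gaps = np.diff(positions)
        mean_gap = gaps.mean()
        if mean_gap <= 0 or np.any(np.abs(gaps - mean_gap) > 0.01 * mean_gap):
            raise GeometryError("non-uniform DICOM slice spacing beyond 1%")
    reader.SetFileNames(names)
    return _from_sitk(reader.Execute())


def read_volume(path: str | Path) -> VolumeImage:
    """Read a NIfTI / MetaImage file or a DICOM series directory.

    Grey values are preserved bit-exactly for integer inputs; spacing and
    anatomical axis labels come from the file metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        return _read_dicom_series(path)
    name = path.name.lower()
    if not any(name.endswith(s) for s in _VOLUME_SUFFIXES):
        raise FormatError(f"unrecognized volume format: {path.name}")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as e:  # SimpleITK wraps parse failures in RuntimeError
        raise FormatError(f"cannot parse {path}: {e}") from e
    return _from_sitk(img)


def write_volume(vol: VolumeImage, path: str | Path) -> None:
    """Write NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd); inverse of read."""
    path = Path(path)
    name = path.name.lower()
    if not any(name.endswith(s) for s in _VOLUME_SUFFIXES):
        raise FormatError(f"unsupported volume output format: {path.name}")
    try:
        sitk.WriteImage(_to_sitk(vol), str(path))
    except RuntimeError as e:
        raise OSError(f"cannot write {path}: {e}") from e


# ---------------------------------------------------------------------------
# Mesh I/O (trimesh)
# ---------------------------------------------------------------------------

def read_mesh(path: str | Path, scale: float = 1.0) -> TriangleMesh:
    """Read STL (binary/ASCII), PLY or OBJ.

    STL stores per-facet vertices; they are merged by exact coordinate match.
    ``scale`` multiplies coordinates (STL carries no unit; mm assumed).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() not in _MESH_SUFFIXES:
        raise FormatError(f"unrecognized mesh format: {path.name}")
    try:
        tm = trimesh.load_mesh(str(path), process=False)
    except Exception as e:
        raise FormatError(f"cannot parse {path}: {e}") from e
    if isinstance(tm, trimesh.Scene):
        geoms = list(tm.geometry.values())
        if not geoms:
            raise FormatError(f"{path} contains no mesh geometry")
        tm = trimesh.util.concatenate(geoms)
    if tm.vertices.size == 0 or tm.faces.size == 0:
        raise FormatError(f"{path} contains no triangles")
    verts = np.asarray(tm.vertices, dtype=float) * float(scale)
    faces = np.asarray(tm.faces)
    # exact-coordinate merge (STL duplicates every facet's vertices)
    uniq, inverse = np.unique(verts, axis=0, return_inverse=True)
    faces = inverse[faces]
    keep = ~((faces[:, 0] == faces[:, 1]) | (faces[:, 1] == faces[:, 2])
             | (faces[:, 0] == faces[:, 2]))
    return TriangleMesh(uniq, faces[keep])


def write_mesh(mesh: TriangleMesh, path: str | Path) -> None:
    """Write STL (binary) or PLY (ascii); byte-stable for repeated writes."""
    if mesh.n_faces == 0 or mesh.n_vertices == 0:
        raise ValidationError("refusing to write an empty mesh")
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix not in (".stl", ".ply"):
        raise FormatError(f"unsupported mesh output format: {path.name}")
    tm = mesh.to_trimesh()
    try:
        if suffix == ".ply":
            data = tm.export(file_type="ply", encoding="ascii")
            if isinstance(data, str):
                data = data.encode()
        else:
            data = tm.export(file_type="stl")
        path.write_bytes(data)
    except OSError:
        raise
    except Exception as e:
        raise OSError(f"cannot write {path}: {e}") from e
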
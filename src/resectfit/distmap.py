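"""Bone-to-implant surface distance maps, colour binning and views.

Distances are asymmetric by design: every *bone* vertex is mapped to its
nearest point on the implant surface, because the method quantifies bone
surplus over the component. Positive sign means the vertex lies on the
outward side of the implant surface ("bone above the CAD model").

The working unit defaults to voxels to match how such tables are reported
(distances "given as mean voxels"); millimetres are always stored
alongside and conversion is a division by the reference voxel size.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DegenerateInputError, UnitError, ValidationError
from .geom import MeshDistanceQuery
from .volio import TriangleMesh, log

#: Bin labels for positive distances [k, k+1) in voxel units, k = 0..7.
BIN_LABELS = ("Light Blue", "Dark Blue", "Red", "Green",
              "Yellow", "Turquoise", "Orange", "Pink")

BIN_COLORS = ("#9bd7ff", "#10408f", "#d62728", "#2ca02c",
              "#ffdf22", "#40e0d0", "#ff8c00", "#ff9ecb")
NEGATIVE_COLOR = "#666666"
OVERFLOW_COLOR = "#1a001a"
IMPLANT_COLOR = "#c8c8c8"


@dataclass
class DistanceMap:
    """Per-bone-vertex signed distance to the implant surface.

    ``normal_z`` optionally carries the proximal (z) component of the
    implant pseudonormal at each vertex's closest feature; downstream
    elevation measurements use it to distinguish surplus *above* the
    bearing surface from sideways protrusion past the implant rim.
    """

    values_mm: np.ndarray
    unit: str = "voxel"
    voxel_size: float = 1.0
    normal_z: np.ndarray | None = None

    def __post_init__(self):
        self.values_mm = np.asarray(self.values_mm, dtype=float).ravel()
        if self.values_mm.size == 0:
            raise DegenerateInputError("empty distance map")
        if self.unit not in ("voxel", "mm"):
            raise UnitError(f"unknown unit {self.unit!r}")
        if self.voxel_size <= 0:
            raise ValidationError("voxel_size must be > 0")

    @property
    def values(self) -> np.ndarray:
        """Signed distances in the map's working unit."""
        if self.unit == "voxel":
            return self.values_mm / self.voxel_size
        return self.values_mm

    def in_unit(self, unit: str) -> "DistanceMap":
        if unit not in ("voxel", "mm"):
            raise UnitError(f"unknown unit {unit!r}")
        return DistanceMap(self.values_mm.copy(), unit, self.voxel_size,
                           None if self.normal_z is None
                           else self.normal_z.copy())


@dataclass
class DistanceBinning:
    """Counts per positive [k, k+1) voxel bin + overflow and negative side."""

    counts: dict
    overflow: int
    negative: int

    def total(self) -> int:
        return sum(self.counts.values()) + self.overflow + self.negative


def signed_distance(bone: TriangleMesh, implant: TriangleMesh,
                    unit: str = "voxel", voxel_size: float = 1.0,
                    query: MeshDistanceQuery | None = None) -> DistanceMap:
    """Signed distance from every bone vertex to the implant surface.

    ``bone`` must already be registered into the implant frame. Pass a
    prebuilt ``query`` to reuse the implant's spatial structure.
    """
    if bone.n_vertices == 0 or implant.n_faces == 0:
        raise DegenerateInputError("empty mesh in signed_distance")
    if query is None:
        query = MeshDistanceQuery(implant)
    signed, _, _, normals = query.signed_query(bone.vertices)
    return DistanceMap(signed, unit=unit, voxel_size=voxel_size,
                       normal_z=normals[:, 2].copy())


def summarize(dm: DistanceMap) -> tuple[float, float, float]:
    """(mean |d|, population sd of |d|, max signed d) in the map's unit.

    The max of the signed values is the "highest elevation" of bone above
    the implant.
    """
    v = dm.values
    a = np.abs(v)
    return float(a.mean()), float(a.std()), float(v.max())


def bin_distances(dm: DistanceMap) -> DistanceBinning:
    """Assign positive voxel-unit distances to the eight [k, k+1) bins."""
    if dm.unit != "voxel":
        raise UnitError("binning is defined on voxel units; convert first")
    v = dm.values
    negative = int((v < 0).sum())
    overflow = int((v >= 8).sum())
    counts = {}
    for k, label in enumerate(BIN_LABELS):
        counts[label] = int(((v >= k) & (v < k + 1)).sum())
    b = DistanceBinning(counts, overflow, negative)
    assert b.total() == v.size
    return b


def export_distances_csv(dm: DistanceMap, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["vertex", "distance_mm", "distance_voxel"])
        for i, d in enumerate(dm.values_mm):
            w.writerow([i, repr(float(d)), repr(float(d / dm.voxel_size))])


def export_distances_ply(mesh: TriangleMesh, dm: DistanceMap,
                         path: str | Path) -> None:
    """ASCII PLY with a per-vertex scalar 'distance' property (mm)."""
    if len(dm.values_mm) != mesh.n_vertices:
        raise ValidationError("distance map does not match mesh")
    lines = ["ply", "format ascii 1.0",
             f"element vertex {mesh.n_vertices}",
             "property float x", "property float y", "property float z",
             "property float distance",
             f"element face {mesh.n_faces}",
             "property list uchar int vertex_indices", "end_header"]
    for v, d in zip(mesh.vertices, dm.values_mm):
        lines.append(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f} {d:.6f}")
    for f in mesh.faces:
        lines.append(f"3 {f[0]} {f[1]} {f[2]}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Standardized views
# ---------------------------------------------------------------------------

def _view_directions() -> dict:
    """Camera directions (unit vectors pointing scene -> camera) and ups.

    World frame: +x medial, +y anterior, +z proximal. Obliques sit at
    +/-45 deg azimuth from anterior, elevated 30 deg.
    """
    el = np.radians(30.0)
    az = np.radians(45.0)

    def sph(azimuth):
        return np.array([np.cos(el) * np.sin(azimuth),
                         np.cos(el) * np.cos(azimuth),
                         np.sin(el)])

    z = np.array([0.0, 0.0, 1.0])
    return {
        "anterior": (np.array([0.0, 1.0, 0.0]), z),
        "posterior": (np.array([0.0, -1.0, 0.0]), z),
        "lateral": (np.array([-1.0, 0.0, 0.0]), z),   # camera lateral, facing medial
        "proximal": (z, np.array([0.0, 1.0, 0.0])),
        "oblique_medial": (sph(+az), z),
        "oblique_lateral": (sph(-az), z),
    }


def _face_colors(dm: DistanceMap, faces: np.ndarray) -> list:
    v = dm.values
    face_val = v[faces].mean(axis=1)
    colors = []
    for d in face_val:
        if d < 0:
            colors.append(NEGATIVE_COLOR)
        elif d >= 8:
            colors.append(OVERFLOW_COLOR)
        else:
            colors.append(BIN_COLORS[int(d)])
    return colors


def render_views(bone: TriangleMesh, implant: TriangleMesh, dm: DistanceMap,
                 out_dir: str | Path, dpi: int = 100) -> list[Path]:
    """Six orthographic PNG renders of the coloured overlay.

    Bone faces are coloured by the distance-bin palette, the implant in
    neutral grey; painter's-algorithm depth sort makes the output
    deterministic for fixed inputs.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.collections import PolyCollection

    if len(dm.values_mm) != bone.n_vertices:
        raise DegenerateInputError("distance map does not match bone mesh")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as e:
        raise OSError(f"cannot write renders to {out_dir}: {e}") from e

    dmv = dm.in_unit("voxel")
    bone_colors = _face_colors(dmv, bone.faces)
    implant_colors = [IMPLANT_COLOR] * implant.n_faces
    all_tri = np.concatenate([bone.vertices[bone.faces],
                              implant.vertices[implant.faces]])
    all_colors = bone_colors + implant_colors

    written = []
    for name, (vdir, up) in _view_directions().items():
        right = np.cross(up, vdir)
        right = right / np.linalg.norm(right)
        up2 = np.cross(vdir, right)
        xy = np.stack([all_tri @ right, all_tri @ up2], axis=-1)  # (F, 3, 2)
        depth = (all_tri @ vdir).mean(axis=1)
        order = np.argsort(depth, kind="stable")                  # far first
        fig, ax = plt.subplots(figsize=(4, 4), dpi=dpi)
        pc = PolyCollection(xy[order],
                            facecolors=[all_colors[i] for i in order],
                            edgecolors="none")
        ax.add_collection(pc)
        lo = xy.reshape(-1, 2).min(axis=0)
        hi = xy.reshape(-1, 2).max(axis=0)
        pad = 0.05 * max(hi - lo)
        ax.set_xlim(lo[0] - pad, hi[0] + pad)
        ax.set_ylim(lo[1] - pad, hi[1] + pad)
        ax.set_aspect("equal")
        ax.axis("off")
        path = out_dir / f"{name}.png"
        fig.savefig(path, dpi=dpi, metadata={"Software": "resectfit"})
        plt.close(fig)
        written.append(path)
    log.info("wrote %d renders to %s", len(written), out_dir)
    return written
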
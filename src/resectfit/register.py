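"""Rigid best-match alignment of the resection mesh onto the implant mesh.

The bone specimen is the *moving* surface, the implant tray the *fixed*
one; all downstream reporting happens in the implant frame. Alignment is
coarse PCA pose initialisation followed by trimmed point-to-triangle ICP.
Trimming matters here: the specimen legitimately overhangs the tray — the
overhang is what the method measures — so a fraction of the worst
correspondences (default 10%) is discarded every iteration to keep the
surplus from biasing the pose.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DegenerateInputError, ValidationError
from .geom import MeshDistanceQuery
from .volio import TriangleMesh, log

_ORTHO_TOL = 1e-9


@dataclass
class RigidTransform:
    """Proper rotation + translation: x -> R @ x + t (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        dev = np.abs(R.T @ R - np.eye(3)).max()
        if dev > 1e-3:
            raise ValidationError("rotation is not orthonormal")
        if dev > _ORTHO_TOL:
            # project onto SO(3); keeps long composition chains honest
            U, _, Vt = np.linalg.svd(R)
            R = U @ np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))]) @ Vt
        if np.linalg.det(R) < 0:
            raise ValidationError("rotation must be proper (det = +1)")
        self.rotation = R
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix."""
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    @classmethod
    def from_matrix(cls, M: np.ndarray) -> "RigidTransform":
        M = np.asarray(M, dtype=float).reshape(4, 4)
        return cls(M[:3, :3], M[:3, 3])

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, degrees."""
        c = np.clip((np.trace(self.rotation) - 1.0) / 2.0, -1.0, 1.0)
        return float(np.degrees(np.arccos(c)))


@dataclass
class RegistrationResult:
    transform: RigidTransform
    rms: float
    iterations: int
    converged: bool

    def __post_init__(self):
        if self.rms < 0:
            raise ValidationError("rms must be >= 0")


def invert(t: RigidTransform) -> RigidTransform:
    return RigidTransform(t.rotation.T, -t.rotation.T @ t.translation)


def compose(t1: RigidTransform, t2: RigidTransform) -> RigidTransform:
    """Transform applying t2 first, then t1."""
    return RigidTransform(t1.rotation @ t2.rotation,
                          t1.rotation @ t2.translation + t1.translation)


def apply_transform(mesh: TriangleMesh, t: RigidTransform) -> TriangleMesh:
    return TriangleMesh(t.apply(mesh.vertices), mesh.faces.copy())


def save_transform(t: RigidTransform, path: str | Path) -> None:
    np.savetxt(path, t.matrix(), fmt="%.17g",
               header="rigid transform, homogeneous 4x4, mm")


def load_transform(path: str | Path) -> RigidTransform:
    return RigidTransform.from_matrix(np.loadtxt(path))


def _subsample(points: np.ndarray, cap: int) -> np.ndarray:
    if len(points) <= cap:
        return points
    idx = np.linspace(0, len(points) - 1, cap).round().astype(int)
    return points[np.unique(idx)]


def _area_centroid(mesh: TriangleMesh) -> np.ndarray:
    tri = mesh.vertices[mesh.faces]
    cent = tri.mean(axis=1)
    area = np.linalg.norm(np.cross(tri[:, 1] - tri[:, 0],
                                   tri[:, 2] - tri[:, 0]), axis=1) / 2.0
    if area.sum() == 0:
        raise DegenerateInputError("mesh has zero surface area")
    return (cent * area[:, None]).sum(axis=0) / area.sum()


def _surface_covariance(mesh: TriangleMesh):
    """Exact area-weighted covariance of the surface (not the vertex cloud).

    Uses edge-midpoint quadrature per triangle, which integrates
    quadratics exactly, so the result is a property of the surface alone
    and independent of how it is triangulated (vertex-cloud covariance is
    badly biased by uneven tessellation, e.g. fan triangulations or
    densely sampled arcs on a CAD outline).
    """
    tri = mesh.vertices[mesh.faces]
    area = np.linalg.norm(np.cross(tri[:, 1] - tri[:, 0],
                                   tri[:, 2] - tri[:, 0]), axis=1) / 2.0
    total = area.sum()
    if total == 0:
        raise DegenerateInputError("mesh has zero surface area")
    mids = np.stack([(tri[:, 0] + tri[:, 1]) / 2.0,
                     (tri[:, 1] + tri[:, 2]) / 2.0,
                     (tri[:, 2] + tri[:, 0]) / 2.0], axis=1)  # (m, 3, 3)
    mu = np.einsum("m,mij->j", area / 3.0, mids) / total
    d = mids - mu
    cov = np.einsum("m,mij,mik->jk", area / 3.0, d, d) / total
    return cov, mu


def _principal_axes(mesh: TriangleMesh) -> np.ndarray:
    cov, _ = _surface_covariance(mesh)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    E = evecs[:, order]
    if evals[0] <= 0 or evals[-1] < 1e-12 * evals[0]:
        raise DegenerateInputError("surface is (near-)coplanar; "
                                   "principal axes undefined")
    if np.linalg.det(E) < 0:
        E[:, 2] = -E[:, 2]
    return E


def initial_align(moving: TriangleMesh, fixed: TriangleMesh,
                  sample_cap: int = 1000,
                  polish_iterations: int = 10) -> RigidTransform:
    """Coarse pose: match area-weighted centroids + principal axes.

    The principal axes come from the exact area-weighted surface
    covariance, so they do not depend on tessellation. Each of the four
    proper axis-sign combinations is scored by its trimmed RMS
    closest-point distance after a short ICP polish (near-symmetric
    shapes make the raw candidate costs almost indistinguishable, while
    the polished costs separate the true pose from its flips); the
    winning raw candidate is returned.
    """
    if moving.n_vertices < 4 or fixed.n_vertices < 4:
        raise DegenerateInputError("need >= 4 vertices on both meshes")
    cm, cf = _area_centroid(moving), _area_centroid(fixed)
    Em = _principal_axes(moving)
    Ef = _principal_axes(fixed)
    query = MeshDistanceQuery(fixed)
    sample = _subsample(moving.vertices, sample_cap)
    best, best_rms = None, np.inf
    for s in ((1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)):
        R = Ef @ np.diag(s) @ Em.T
        t = RigidTransform(R, cf - R @ cm)
        if polish_iterations > 0:
            _, rms, _, _ = _icp_core(sample, query, t,
                                     max_iterations=polish_iterations,
                                     tol=1e-9, trim_fraction=0.1)
        else:
            d, _, _ = query.query(t.apply(sample))
            rms = float(np.sqrt(np.mean(d ** 2)))
        if rms < best_rms:
            best, best_rms = t, rms
    log.debug("initial_align rms = %.4f mm", best_rms)
    return best


def icp(moving: TriangleMesh, fixed: TriangleMesh,
        init: RigidTransform | None = None,
        max_iterations: int = 100, tol: float = 1e-6,
        trim_fraction: float = 0.1,
        sample_cap: int = 2000) -> RegistrationResult:
    """Trimmed iterative-closest-point rigid registration.

    Correspondences are moving vertices to the nearest point *on* the fixed
    mesh's triangles (not nearest vertex). Each iteration discards the
    ``trim_fraction`` worst correspondences before the least-squares rigid
    update — except correspondences beyond the implant's distal face,
    which are never discarded (see ``_icp_core``) — and stops when the
    trimmed RMS improves by less than ``tol`` mm. The trimmed RMS never
    increases between accepted iterations.
    """
    if not np.isfinite(moving.vertices).all() or not np.isfinite(fixed.vertices).all():
        raise ValidationError("non-finite vertex coordinates")
    if not (0.0 <= trim_fraction < 0.5):
        raise ValidationError("trim_fraction must lie in [0, 0.5)")
    if max_iterations < 1:
        raise ValidationError("max_iterations must be >= 1")
    t = init if init is not None else initial_align(moving, fixed)
    query = MeshDistanceQuery(fixed)
    pts = _subsample(moving.vertices, sample_cap)
    t, rms, it, converged = _icp_core(pts, query, t, max_iterations, tol,
                                      trim_fraction)
    return RegistrationResult(t, rms, it, converged)


def _icp_core(pts: np.ndarray, query: MeshDistanceQuery, t: RigidTransform,
              max_iterations: int, tol: float, trim_fraction: float):
    """Trimmed ICP inner loop with seating-aware trimming.

    Each iteration discards the ``trim_fraction`` worst correspondences,
    except that a correspondence lying beyond the implant's *distal*
    side (positive signed distance with the closest feature facing
    distally) is never discarded. The specimen may overhang the tray
    proximally or sideways — that surplus is the measurand — but the
    tray seats flat on the cut face, so bone past the distal face marks
    a wrong pose and must keep pulling the fit back rather than be
    trimmed away as an outlier. Without this protection a
    proximal-surface-wide wedge tilts the pose until the specimen sinks
    through the tray's distal face.
    """
    n = len(pts)
    n_trim = max(0, min(int(np.floor(n * trim_fraction)), n - 3))
    prev_rms = np.inf
    converged = False
    it = 0
    for it in range(1, max_iterations + 1):
        cur = t.apply(pts)
        ds, cp, _, nrm = query.signed_query(cur)
        d = np.abs(ds)
        protected = (ds > 1e-9) & (nrm[:, 2] < -0.5)   # beyond the distal face
        reject = np.zeros(n, dtype=bool)
        if n_trim > 0:
            rejectable_d = np.where(protected, -np.inf, d)
            worst = np.argsort(rejectable_d, kind="stable")[n - n_trim:]
            reject[worst[rejectable_d[worst] > -np.inf]] = True
        keep = np.flatnonzero(~reject)
        rms = float(np.sqrt(np.mean(d[keep] ** 2)))
        if rms > prev_rms + 1e-12:   # should not happen; keep the better pose
            it -= 1
            break
        if prev_rms - rms < tol:
            prev_rms = min(prev_rms, rms)
            converged = True
            break
        prev_rms = rms
        # least-squares rigid update (Kabsch) on trimmed correspondences
        p = cur[keep]
        q = cp[keep]
        pc, qc = p.mean(axis=0), q.mean(axis=0)
        H = (p - pc).T @ (q - qc)
        U, _, Vt = np.linalg.svd(H)
        d3 = np.sign(np.linalg.det(Vt.T @ U.T))
        R = Vt.T @ np.diag([1.0, 1.0, d3]) @ U.T
        upd = RigidTransform(R, qc - R @ pc)
        t = compose(upd, t)
    return t, (prev_rms if np.isfinite(prev_rms) else 0.0), it, converged
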
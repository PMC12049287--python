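"""Isosurface extraction and mesh metrics.

The binary specimen mask becomes a closed triangle surface via marching
cubes at iso-level 0.5 (Lewiner variant of
``skimage.measure.marching_cubes``, a deterministic, documented ambiguity
resolution). The {0,1} field is first anti-aliased with a small Gaussian
(default sigma = 1 voxel): marching cubes on a raw binary field produces
45-degree stair-step facets whose total area overestimates a smooth
surface by roughly 10% without converging away at finer voxels, while the
0.5-level set of the blurred indicator tracks both area and enclosed
volume of the underlying shape to well under 1% on a digitised sphere.
Masks too small to survive the blur fall back to the raw field. Vertices
land in world mm coordinates. Optional Taubin mesh smoothing is also
available but off by default.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import measure
from trimesh import smoothing as _tsmooth

from .errors import DegenerateInputError, ValidationError
from .segment import BinaryMask
from .volio import TriangleMesh, log


def extract_surface(mask: BinaryMask, iso: float = 0.5,
                    antialias_sigma: float = 1.0) -> TriangleMesh:
    """Closed, outward-oriented surface of a binary mask at ``iso``.

    The mask is padded on every side so surfaces touching the array
    border still close; ``antialias_sigma`` (voxels, 0 disables) controls
    the indicator-field blur described in the module docstring.
    """
    if not (0.0 < iso < 1.0):
        raise ValidationError("iso level must lie in (0, 1)")
    if antialias_sigma < 0:
        raise ValidationError("antialias_sigma must be >= 0")
    if not mask.data.any():
        raise DegenerateInputError("cannot extract surface from empty mask")
    pad = max(2, int(np.ceil(2 * antialias_sigma)))
    padded = np.pad(mask.data, pad).astype(np.float32)
    field = padded
    if antialias_sigma > 0:
        blurred = ndimage.gaussian_filter(padded, antialias_sigma)
        if blurred.max() > iso:
            field = blurred
        else:
            log.warning("mask too small for anti-aliasing; raw field used")
    verts, faces, _, _ = measure.marching_cubes(
        field, level=iso, spacing=tuple(mask.spacing), method="lewiner")
    verts = verts - pad * mask.spacing  # undo the padding
    # array axes -> world axes, then shift by origin
    P = np.zeros((3, 3))
    from .volio import AXIS_LABELS
    for j, lab in enumerate(mask.axes):
        P[AXIS_LABELS.index(lab), j] = 1.0
    verts = verts @ P.T + mask.origin
    mesh = TriangleMesh(verts, faces)
    return _orient_outward(mesh)


def _orient_outward(mesh: TriangleMesh) -> TriangleMesh:
    """Flip face winding if the signed enclosed volume is negative."""
    if _signed_volume(mesh) < 0:
        return TriangleMesh(mesh.vertices, mesh.faces[:, ::-1])
    return mesh


def _signed_volume(mesh: TriangleMesh) -> float:
    v = mesh.vertices
    a, b, c = v[mesh.faces[:, 0]], v[mesh.faces[:, 1]], v[mesh.faces[:, 2]]
    return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)


def smooth_mesh(mesh: TriangleMesh, iterations: int = 10,
                relaxation: float = 0.1) -> TriangleMesh:
    """Taubin (shrink/inflate) smoothing; topology unchanged.

    ``relaxation`` is the positive step lambda; the inflation step nu is the
    standard pass-band pairing ``nu = -lambda / (1 - 0.1*lambda)`` slightly
    overshooting lambda, which keeps volume change small.
    """
    if iterations < 0:
        raise ValidationError("iterations must be >= 0")
    if not (0.0 < relaxation < 1.0):
        raise ValidationError("relaxation must lie in (0, 1)")
    if iterations == 0:
        return TriangleMesh(mesh.vertices.copy(), mesh.faces.copy())
    tm = mesh.to_trimesh()
    if not tm.is_watertight:
        log.warning("smoothing an open mesh; volume will not be conserved")
    nu = -relaxation / (1.0 - 0.1 * relaxation)
    _tsmooth.filter_taubin(tm, lamb=relaxation, nu=nu, iterations=iterations)
    return TriangleMesh(np.asarray(tm.vertices), mesh.faces.copy())


def mesh_metrics(mesh: TriangleMesh) -> tuple[float, float | None]:
    """(surface area mm^2, enclosed volume mm^3 or None if the mesh is open).

    Volume via the divergence theorem (sum of signed tetrahedra against the
    origin), reported as an absolute value.
    """
    v = mesh.vertices
    a, b, c = v[mesh.faces[:, 0]], v[mesh.faces[:, 1]], v[mesh.faces[:, 2]]
    area = float(np.linalg.norm(np.cross(b - a, c - a), axis=1).sum() / 2.0)
    if not mesh.is_closed():
        log.warning("mesh is not closed; enclosed volume undefined")
        return area, None
    return area, abs(_signed_volume(mesh))
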
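"""Synthetic resection phantoms with analytic ground truth.

The phantom emulates the geometry the method measures, not an anatomic
tibia: the medial-plateau resection specimen is a D-shaped prism (straight
border toward the knee centre, rounded border medially, like a tibial
tray footprint) whose proximal surface is either flat ("rectangular"
specimen, the shape a 3-degree varus cut produces on a ~3-degree varus
joint line) or a wedge rising linearly from the central edge to
``ML * tan(angle)`` at the medial edge (the shape a 0-degree cut
produces). The base slab is congruent with the generated implant tray —
a zero-surplus construction, so every elevation a perfectly registered
pipeline reports is attributable to the wedge (plus voxelisation noise).

The D-shaped (not symmetric rounded-rectangular) footprint is deliberate:
an AP-uniform wedge on a symmetric footprint would leave a 180-degree
in-plane rotation that swaps medial and central sides at nearly identical
registration cost.

Grey levels model cone-beam CT populations: background, spongious bone,
optionally a cortical shell, and a brighter sclerotic patch on the distal
cut face; i.i.d. Gaussian noise models acquisition noise. All randomness
derives from one seed via ``numpy.random.SeedSequence`` spawning.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .register import RigidTransform
from .volio import CANONICAL_AXES, TriangleMesh, VolumeImage


@dataclass
class PhantomSpec:
    """Parameters of one synthetic resection specimen + matching tray."""

    wedge_angle_deg: float = 0.0        # 0 = rectangular specimen
    ml_width: float = 25.0              # mm, medial-lateral footprint extent
    ap_depth: float = 40.0              # mm, anterior-posterior extent
    base_thickness: float = 3.0         # mm, congruent with tray thickness
    corner_radius: float = 6.0          # mm, posteromedial corner (0 = box)
    corner_radius_anterior: float = 2.5  # mm, anteromedial corner
    voxel: float = 0.5                  # mm, isotropic spacing
    grey_background: float = 0.0
    grey_spongious: float = 120.0
    grey_cortical: float = 200.0
    grey_sclerotic: float = 280.0
    shell_cortical: bool = False        # paint a 1-voxel cortical shell
    noise_sd: float = 10.0              # grey units
    sclerotic_fraction: float = 0.0     # of the distal-face cross-section
    tilt_deg: float = 0.0               # rotation about the AP axis
    container: bool = False             # add a preservation-box shell
    seed: int = 0

    def __post_init__(self):
        if min(self.ml_width, self.ap_depth, self.base_thickness,
               self.voxel) <= 0:
            raise ValidationError("dimensions and voxel size must be > 0")
        if not (0.0 <= self.wedge_angle_deg < 45.0):
            raise ValidationError("wedge angle must lie in [0, 45) degrees")
        if not (0.0 <= self.sclerotic_fraction < 1.0):
            raise ValidationError("sclerotic fraction must lie in [0, 1)")
        if not (self.grey_background < self.grey_spongious
                < self.grey_sclerotic):
            raise ValidationError("grey levels must be ordered "
                                  "background < spongious < sclerotic")
        if min(self.corner_radius, self.corner_radius_anterior) < 0 \
                or self.corner_radius + self.corner_radius_anterior > self.ap_depth \
                or max(self.corner_radius, self.corner_radius_anterior) > self.ml_width:
            raise ValidationError("corner radii incompatible with footprint")


@dataclass
class PhantomTruth:
    """Closed-form ground truth accompanying a generated phantom."""

    bone_voxel_count: int
    analytic_volume_mm3: float
    medial_max_elevation_mm: float      # ML * tan(angle)
    central_max_elevation_mm: float     # (ML/2) * tan(angle), at the split
    sclerotic_fraction: float
    tilt: RigidTransform | None
    distal_slice_index: int
    footprint_area_mm2: float = 0.0

    def elevations_voxel(self, voxel: float) -> tuple[float, float]:
        return (self.medial_max_elevation_mm / voxel,
                self.central_max_elevation_mm / voxel)


# ---------------------------------------------------------------------------
# Footprint geometry (shared by tray mesh and specimen voxelisation)
# ---------------------------------------------------------------------------

def _footprint_polygon(spec: PhantomSpec, n_arc: int = 8) -> np.ndarray:
    """CCW convex polygon of the D-shaped footprint in the ML-AP plane.

    Central (lateral-facing) border straight at x = -ML/2; medial border
    at x = +ML/2 with a posteromedial corner of ``corner_radius`` and an
    anteromedial corner of ``corner_radius_anterior``. Unequal radii break
    the AP mirror symmetry, as on a real tray, so flipped poses cost RMS.
    """
    w2 = spec.ml_width / 2.0
    d2 = spec.ap_depth / 2.0
    rp = spec.corner_radius
    ra = spec.corner_radius_anterior
    pts = [(-w2, d2), (-w2, -d2)]
    if rp == 0:
        pts.append((w2, -d2))
    else:
        pts.append((w2 - rp, -d2))
        cx, cy = w2 - rp, -d2 + rp
        for k in range(1, n_arc + 1):
            a = -np.pi / 2 + (np.pi / 2) * k / n_arc
            pts.append((cx + rp * np.cos(a), cy + rp * np.sin(a)))
    if ra == 0:
        pts.append((w2, d2))
    else:
        pts.append((w2, d2 - ra))
        cx, cy = w2 - ra, d2 - ra
        for k in range(1, n_arc + 1):
            a = 0.0 + (np.pi / 2) * k / n_arc
            pts.append((cx + ra * np.cos(a), cy + ra * np.sin(a)))
    return np.asarray(pts, dtype=float)


def _polygon_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return float(0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def footprint_area_analytic(spec: PhantomSpec) -> float:
    """Exact area of the D-shaped footprint (two rounded medial corners)."""
    deficit = sum(r * r - np.pi * r * r / 4.0
                  for r in (spec.corner_radius, spec.corner_radius_anterior))
    return spec.ml_width * spec.ap_depth - deficit


def _points_in_polygon(x: np.ndarray, y: np.ndarray,
                       poly: np.ndarray) -> np.ndarray:
    """Point-in-convex-polygon (CCW): all edge cross products >= 0."""
    inside = np.ones(x.shape, dtype=bool)
    n = len(poly)
    for i in range(n):
        x0, y0 = poly[i]
        x1, y1 = poly[(i + 1) % n]
        inside &= ((x1 - x0) * (y - y0) - (y1 - y0) * (x - x0)) >= 0
    return inside


# ---------------------------------------------------------------------------
# Implant tray
# ---------------------------------------------------------------------------

def make_implant_mesh(spec: PhantomSpec) -> TriangleMesh:
    """Closed, outward-oriented tray: footprint polygon extruded in z.

    The tray occupies z in [0, base_thickness]; its distal face (z = 0)
    models the underside seated on the cut, centred on the world origin
    in ML-AP. Deterministic for a fixed spec.
    """
    poly = _footprint_polygon(spec)
    n = len(poly)
    t = spec.base_thickness
    bottom = np.column_stack([poly, np.zeros(n)])
    top = np.column_stack([poly, np.full(n, t)])
    verts = np.vstack([bottom, top])
    faces = []
    for i in range(1, n - 1):           # bottom fan, normal -z
        faces.append([0, i + 1, i])
    for i in range(1, n - 1):           # top fan, normal +z
        faces.append([n, n + i, n + i + 1])
    for i in range(n):                  # side quads, outward
        j = (i + 1) % n
        faces.append([i, j, n + j])
        faces.append([i, n + j, n + i])
    return TriangleMesh(verts, np.asarray(faces))


# ---------------------------------------------------------------------------
# Specimen volume
# ---------------------------------------------------------------------------

def _prism_height(spec: PhantomSpec, x: np.ndarray) -> np.ndarray:
    """Total specimen height (mm) above z=0 at ML coordinate x."""
    h = np.full(x.shape, spec.base_thickness, dtype=float)
    if spec.wedge_angle_deg > 0:
        rise = np.tan(np.radians(spec.wedge_angle_deg))
        h = h + np.clip(x + spec.ml_width / 2.0, 0.0, None) * rise
    return h


def analytic_prism_volume(spec: PhantomSpec) -> float:
    """Closed-form specimen volume: base slab + (for a box footprint) wedge.

    The wedge volume uses the rectangular footprint cross-section
    0.5 * ML^2 * tan(angle) * AP corrected for the rounded medial corners
    (the wedge is tallest exactly where the corners cut material away);
    the correction integrates the wedge height over the two corner
    regions.
    """
    area = footprint_area_analytic(spec)
    vol = area * spec.base_thickness
    if spec.wedge_angle_deg > 0:
        rise = np.tan(np.radians(spec.wedge_angle_deg))
        W, D = spec.ml_width, spec.ap_depth
        vol += 0.5 * W * W * rise * D
        for r in (spec.corner_radius, spec.corner_radius_anterior):
            if r > 0:
                # material removed by a rounded corner, weighted by wedge
                # height h(x) = (x + W/2)*rise; corner occupies
                # x in [W/2 - r, W/2] with missing AP width
                # m(x) = r - sqrt(r^2 - (x - (W/2 - r))^2);
                # smooth 1D integral evaluated numerically.
                xs = np.linspace(W / 2 - r, W / 2, 2049)
                m = r - np.sqrt(np.clip(r * r - (xs - (W / 2 - r)) ** 2,
                                        0, None))
                h = (xs + W / 2) * rise
                vol -= np.trapezoid(m * h, xs)
    return float(vol)


def make_resection_volume(spec: PhantomSpec) -> tuple[VolumeImage, PhantomTruth]:
    """Voxelised specimen + closed-form truth.

    Voxel centres inside the prism get bone grey values; Gaussian noise is
    added everywhere. Optional: tilt about the AP axis, a hollow
    container shell well outside the specimen (removed by the documented
    crop box), and a sclerotic patch on the distal face.
    """
    # sub-stream 0 reserved for geometry perturbations (unused today)
    _, ss_noise, ss_scl = np.random.SeedSequence(spec.seed).spawn(3)
    rng_noise = np.random.default_rng(ss_noise)
    rng_scl = np.random.default_rng(ss_scl)
    h = spec.voxel
    margin = 4 * h
    wedge_max = spec.ml_width * np.tan(np.radians(spec.wedge_angle_deg))
    x0 = -spec.ml_width / 2 - margin
    y0 = -spec.ap_depth / 2 - margin
    z0 = -margin
    nx = int(np.ceil((spec.ml_width + 2 * margin) / h))
    ny = int(np.ceil((spec.ap_depth + 2 * margin) / h))
    nz = int(np.ceil((spec.base_thickness + wedge_max + 2 * margin) / h))
    xs = x0 + (np.arange(nx) + 0.5) * h
    ys = y0 + (np.arange(ny) + 0.5) * h
    zs = z0 + (np.arange(nz) + 0.5) * h
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    poly = _footprint_polygon(spec)
    foot = _points_in_polygon(X, Y, poly)
    height = _prism_height(spec, X)
    Z = zs[None, None, :]
    inside = (foot[:, :, None] & (Z >= 0.0)
              & (Z < height[:, :, None]))
    count = int(inside.sum())

    grey = np.full((nx, ny, nz), spec.grey_background, dtype=float)
    grey[inside] = spec.grey_spongious
    if spec.shell_cortical:
        interior = ndimage.binary_erosion(inside)
        grey[inside & ~interior] = spec.grey_cortical

    # sclerotic patch: contiguous blob in the distal-most bone slab
    distal_k = int(np.searchsorted(zs, 0.0))
    scl_fraction_true = 0.0
    if spec.sclerotic_fraction > 0:
        slab = inside[:, :, distal_k]
        idx = np.argwhere(slab)
        n_scl = int(round(spec.sclerotic_fraction * len(idx)))
        if n_scl > 0:
            seed_pt = idx[rng_scl.integers(len(idx))]
            order = np.argsort(np.linalg.norm(idx - seed_pt, axis=1),
                               kind="stable")
            chosen = idx[order[:n_scl]]
            blob = np.zeros_like(slab)
            blob[chosen[:, 0], chosen[:, 1]] = True
            depth = min(3, nz - distal_k)     # a few voxels thick
            for dk in range(depth):
                sl = inside[:, :, distal_k + dk] & blob
                g = grey[:, :, distal_k + dk]
                g[sl] = spec.grey_sclerotic
            scl_fraction_true = n_scl / len(idx)

    if spec.noise_sd > 0:
        grey = grey + rng_noise.normal(0.0, spec.noise_sd, grey.shape)

    if spec.container:
        # hollow box shell hugging the volume border; eliminated by
        # cropping 3 voxels off every face
        shell = np.zeros_like(grey, dtype=bool)
        shell[[0, -1], :, :] = True
        shell[:, [0, -1], :] = True
        shell[:, :, [0, -1]] = True
        grey[shell] = spec.grey_cortical

    tilt_t = None
    if spec.tilt_deg != 0.0:
        a = np.radians(spec.tilt_deg)
        R = np.array([[np.cos(a), 0.0, np.sin(a)],
                      [0.0, 1.0, 0.0],
                      [-np.sin(a), 0.0, np.cos(a)]])
        tilt_t = RigidTransform(R, np.zeros(3))
        grey = ndimage.rotate(grey, spec.tilt_deg, axes=(0, 2), reshape=True,
                              order=1, mode="constant",
                              cval=spec.grey_background)

    # origin = world position of voxel (0,0,0)'s centre, per the package
    # convention index -> origin + index*spacing
    vol = VolumeImage(grey, np.full(3, h),
                      np.array([x0, y0, z0]) + h / 2.0, CANONICAL_AXES)
    truth = PhantomTruth(
        bone_voxel_count=count,
        analytic_volume_mm3=analytic_prism_volume(spec),
        medial_max_elevation_mm=wedge_max,
        central_max_elevation_mm=wedge_max / 2.0,
        sclerotic_fraction=scl_fraction_true,
        tilt=tilt_t,
        distal_slice_index=distal_k,
        footprint_area_mm2=_polygon_area(poly),
    )
    return vol, truth


# ---------------------------------------------------------------------------
# Stand-alone sclerosis slice
# ---------------------------------------------------------------------------

def make_sclerosis_slice(fraction: float, mask_radius: int = 56,
                         spongious_mu: float = 120.0,
                         sclerotic_mu: float = 280.0,
                         noise_sd: float = 15.0,
                         seed: int = 0):
    """(grey slice, mask, true fraction) with an exact sclerotic pixel count.

    The mask is a filled disk; exactly ``round(fraction * mask_size)``
    pixels, grown as a contiguous blob from a seeded point, draw from the
    sclerotic grey population, the rest from the spongious one.
    """
    if not (0.0 <= fraction < 1.0):
        raise ValidationError("fraction must lie in [0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = 2 * mask_radius + 5
    yy, xx = np.mgrid[:n, :n]
    c = n // 2
    mask = (xx - c) ** 2 + (yy - c) ** 2 <= mask_radius ** 2
    idx = np.argwhere(mask)
    n_scl = int(round(fraction * len(idx)))
    grey = np.zeros((n, n))
    grey[mask] = spongious_mu
    if n_scl > 0:
        seed_pt = idx[rng.integers(len(idx))]
        order = np.argsort(np.linalg.norm(idx - seed_pt, axis=1), kind="stable")
        chosen = idx[order[:n_scl]]
        grey[chosen[:, 0], chosen[:, 1]] = sclerotic_mu
    if noise_sd > 0:
        grey = grey + rng.normal(0.0, noise_sd, grey.shape)
    return grey, mask, (n_scl / len(idx) if len(idx) else 0.0)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def make_cohort(n_per_group: int, spec_group0: PhantomSpec,
                spec_group3: PhantomSpec, seed: int = 0) -> list[dict]:
    """Two groups of phantoms with per-specimen +/-5% dimension jitter.

    Group labels follow the *resection angle* naming: "0deg" specimens are
    the ones the 0-degree cut hypothesis predicts (wedge-shaped, pass
    ``spec_group0`` with a wedge angle), "3deg" the rectangular ones.
    Returns dicts with keys id, group, volume, implant, truth, spec.
    """
    if n_per_group < 1:
        raise ValidationError("n_per_group must be >= 1")
    out = []
    children = np.random.SeedSequence(seed).spawn(2 * n_per_group)
    for i in range(2 * n_per_group):
        group = "0deg" if i < n_per_group else "3deg"
        base = spec_group0 if i < n_per_group else spec_group3
        ss = children[i]
        rng = np.random.default_rng(ss)
        jitter = rng.uniform(0.95, 1.05, size=3)
        sub_seed = int(ss.generate_state(1)[0] % (2 ** 31))
        spec = replace(base,
                       ml_width=base.ml_width * jitter[0],
                       ap_depth=base.ap_depth * jitter[1],
                       base_thickness=base.base_thickness * jitter[2],
                       seed=sub_seed)
        vol, truth = make_resection_volume(spec)
        tray = make_implant_mesh(spec)
        out.append({"id": f"{group}_{i % n_per_group:02d}", "group": group,
                    "volume": vol, "implant": tray, "truth": truth,
                    "spec": spec})
    return out
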
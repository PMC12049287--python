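# Methods

This note documents the models, numerical choices and limitations behind
`resectfit`. The package quantifies the fit between a resected tibial
bone slab and the unicompartmental tray meant to sit on it; everything
below is written for someone who wants to trust (or challenge) a number
the pipeline prints.

## Coordinate conventions

One right-handed, mm-unit world frame is used throughout: +x medial,
+y anterior, +z proximal. Voxel index `(i, j, k)` of a volume maps to
`origin + (i·s0, j·s1, k·s2)` along the anatomically labelled axes
(`origin` is the centre of voxel `(0,0,0)`; indices 0-based; the positive
index direction is the positive anatomical direction). Axis labels
round-trip through the direction-cosine matrix of NIfTI/MetaImage files
as a signed permutation; oblique acquisitions are rejected rather than
silently resampled. DICOM series order is resolved from slice positions,
never file names, and slice spacing must be uniform within 1%.

## Segmentation

Bone is marked by a half-open grey band `[low, high)` — half-open so
stacked bands (as in sclerosis scoring) never double-count. The
automated alternative to a fixed threshold is Otsu's criterion with one
refinement: for well-separated populations the between-class variance is
flat across the empty histogram gap, and taking the *first* maximising
bin (the common library behaviour) parks the threshold at the edge of
the lower population's tail. The implementation returns the midpoint of
the maximising plateau, i.e. the middle of the gap, which is what an
operator choosing interactively would do. The threshold used is logged.

The largest connected component (26-connectivity by default, the most
permissive choice for a specimen removed in one piece) removes debris;
ties are broken by the component containing the lexicographically
smallest voxel index. Volumes are voxel counts, physical volume =
count x voxel volume.

## Surface extraction

Marching cubes (the deterministic Lewiner variant) runs at iso-level 0.5
of the binary mask after a Gaussian anti-aliasing blur of sigma = 1
voxel. The blur is deliberate: on the raw {0,1} field marching cubes
produces 45° stair-step facets whose total area overestimates a smooth
surface by roughly 10% *independently of resolution*, while the 0.5
level set of the blurred indicator tracks a digitised sphere's analytic
area and volume to ~0.2%. Masks too small to survive the blur (a blurred
maximum at or below the iso level) fall back to the raw field, so even a
single-voxel mask yields a closed mesh. Extracted meshes are closed and
re-oriented outward (positive signed volume) if needed.

Optional Taubin smoothing (shrink/inflate pairs; pass-band pairing
`nu = -lambda/(1 - 0.1 lambda)`) is available but off by default: the
interactive workflow this reproduces does not report smoothing
parameters, so none can be claimed faithful. At the default 10
iterations with lambda = 0.1 the enclosed volume changes by < 2% on the
sphere phantom.

Mesh metrics: area as the triangle-area sum; enclosed volume by the
divergence theorem (signed tetrahedra), reported absolute, and absent
for open meshes.

## Registration

The bone is the moving surface, the implant fixed; all reporting happens
in the implant frame.

**Initialisation.** Area-weighted centroids are matched and the
principal axes of the *surface* covariance aligned. The covariance uses
exact triangle edge-midpoint quadrature (exact for quadratics), because
vertex-cloud PCA is badly biased by uneven tessellation — a fan
triangulation concentrates vertices at its apex and rotated the tray's
axes by 16° in early testing. Eigen-axes leave four proper sign
combinations; near-symmetric shapes make their raw costs almost
indistinguishable, so each candidate is polished with 10 trimmed-ICP
iterations and the candidate whose polished trimmed RMS is lowest wins.
Surfaces whose smallest covariance eigenvalue vanishes (coplanar) are
rejected as degenerate.

**Trimmed ICP.** Correspondences go from moving vertices to the nearest
point *on* the fixed triangles (not the nearest vertex — bone meshes are
much denser than CAD trays). Up to 2000 evenly-spaced vertices are used
per iteration. Each iteration discards the worst `trim_fraction`
(default 0.1) of correspondences before the closed-form least-squares
(Kabsch/SVD) rigid update; iteration stops when the trimmed RMS improves
by less than `tol` (default 1e-6 mm) or after `max_iterations` (default
100). The trimmed RMS never increases between accepted iterations.

**Seating-aware trimming.** Trimming exists to tolerate the overhang the
method is designed to measure — but a wedge surplus can cover the entire
proximal surface, far more than any fixed trim fraction. Under plain
trimming the least-squares update then tilts the specimen to split the
wedge, sinking it through the tray's *distal* face — a configuration the
physics forbids, since the tray seats flat on the cut. Correspondences
beyond the distal face (positive signed distance whose closest implant
feature faces distally) are therefore never trimmed; they keep pulling
the pose back. With this rule a 3° wedge leaves a residual tilt of about
1° instead of 2.6°, and tray-perturbation recovery stays exact. Note the
best-match alignment still absorbs part of any full-surface wedge
(roughly a third at 3°); measured elevations are surpluses *in the
best-match frame*, exactly as in the clinical workflow, and are expected
to sit somewhat below the pure-geometry closed form.

Transforms are proper rotations (orthonormality enforced to 1e-9 by SVD
projection) plus translations, serialized as plain-text homogeneous 4x4
matrices. No randomness is involved anywhere in registration.

## Distance mapping

Distances are asymmetric by design — bone to implant only, because the
measurand is bone surplus over the component. The kernel finds, for
every bone vertex, the exact closest point over all implant triangles:
KD-tree candidate pruning over triangle centroids (with a rigorous
radius bound, so pruning is exact) above 1024 faces, chunked exhaustive
evaluation below. The per-pair closest point uses the standard
Voronoi-region (barycentric clamp) algorithm, vectorised.

Signs come from angle-weighted pseudonormals of the closest feature
(face, edge or vertex), the standard construction that classifies
inside/outside correctly where bare face normals fail (edges, vertices).
The z-component of that feature normal is stored per vertex: downstream
elevation measurements use it to separate surplus *above* the bearing
surface from sideways protrusion past the tray rim.

The working unit defaults to voxels (matching how such results are
tabulated); millimetres are always stored alongside, conversion is a
division by the reference voxel size (the mean spacing; anisotropic
spacing triggers a warning). Positive voxel-unit distances fall into
eight half-open bins `[k, k+1)`, k = 0..7, labelled Light Blue, Dark
Blue, Red, Green, Yellow, Turquoise, Orange, Pink, with explicit
overflow (>= 8) and negative-side counts; the counts always sum to the
vertex count. Summary statistics are the mean and *population* sd of
|d| and the maximum of the signed values (the highest elevation).

Six standardized orthographic views (anterior, posterior, lateral,
proximal, and two obliques at ±45° azimuth from anterior, 30° elevation
— the oblique angles are this package's documented choice) are rendered
with painter's-algorithm depth sorting; output PNGs are byte-identical
across runs for fixed inputs.

## Compartment analysis

The implant footprint's bounding rectangle in the ML-AP plane, dilated
by one voxel, is quartered at configurable split fractions (default the
midpoints) into AMM / AMC / PMM / PMC, the four-quadrant adaptation of
the Krause tibial-plateau segmentation to the resected medial plateau.
Bone vertices project into the rectangle; ties on a split plane go to
the anterior / medial side; vertices outside the dilated rectangle are
labelled `outside`. Which side of the ML axis is medial comes from the
anatomical frame, never guessed from geometry.

Each quadrant reports a maximal elevation twice — once in its own
anterior sub-half and once in its posterior sub-half (sub-split at the
quadrant's AP midpoint, fixed by footprint geometry). This mirrors a
rater measuring every quadrant on both an anterior and a posterior
image; `total = anterior + posterior` holds exactly by construction.
Elevation means bone above the bearing surface: negative distances clip
to zero, and vertices whose closest implant feature does not face
proximally (feature-normal z below 0.5, a 60° cone) do not count —
a vertex poking sideways past the rim is overhang, not elevation.
Without this rule, stair-step spikes at the tray rim dominate the maxima
of well-fitting specimens.

Summary quantities: per-specimen **total mismatch** is defined here as
the mean of the four quadrant totals (the source tables are ambiguous on
this point — their "all" row is not the mean of the printed compartment
means — so this is a documented package definition, not a claim about
the original); the **quotient** is `(AMC + PMC) / (AMM + PMM)` on
totals, flagged undefined when the medial denominator is zero (a
specimen with no medial surplus has no meaningful ratio; such specimens
are excluded from quotient statistics). The quotient is invariant to
scaling all distances.

## Sclerosis scoring

The distal cut face is the surface the implant bonds to; dense
(sclerotic) bone there disfavours ingrowth. Scoring proceeds on the most
distal usable axial slice after rotation correction:

* **Rotation correction** fits a least-squares plane to the distal
  surface voxels (mask voxels whose distal neighbour is background; at
  least 16 required) and resamples the volume so the plane normal is
  axial — linear interpolation for grey values, nearest-neighbour for
  the mask.
* **Slice selection** walks proximally from the distal end and takes the
  first slice holding at least a configurable fraction (default 50%) of
  the maximal per-slice cross-section, guarding against a ragged,
  partial last slice.
* **Cut-off** at `min + f (max − min)` over in-mask grey values with
  f = 2/3 by default — the "upper third of the grey values" read as
  range-relative over the analysed slice. Both the fraction and the
  interpretation (`range` | `quantile`) are configurable because no
  calibrated cut-off exists for cone-beam CT grey values. Pixels at or
  above the cut-off are sclerotic; the percentage is
  `sclerotic / (sclerotic + spongious) x 100`. Counts always conserve,
  and the whole rule is invariant to affine grey rescaling.
* **Two-population guard** (pipeline scoring, `score_slice`): a
  range-relative cut-off presumes two populations. On a slice containing
  only spongious bone plus Gaussian noise, the extremes of ~10^4 samples
  span about 7.7 noise sigmas, so the upper-third mark lands ~1.3 sigma
  above the mean and falsely labels ~10% of pixels — at any noise level,
  since the rule is scale-invariant. The guard compares the in-mask
  range to a robust lower-population scale, `(P25 − P5)/0.971` (exact
  for a Gaussian tail): one population keeps the ratio below ~9, a
  separated sclerotic population pushes it above ~13, and the default
  cut of 11 separates the regimes; below it the slice is reported
  sclerosis-free. This is the package's explicit stand-in for the
  clinician's visual judgement that sclerosis is present at all. The
  low-level threshold/count operations apply the bare rule without the
  guard.

## Synthetic phantoms

The generator produces the *geometry the method measures*, not an
anatomic tibia: the measurands (wedge surplus, quotient, sclerosis
fraction) are geometry-level, and anatomic realism would add
unverifiable complexity.

A specimen is a D-shaped prism — straight border toward the knee centre,
rounded medial border, like a tray footprint — of base thickness equal
to the generated tray's thickness ("zero-surplus construction": a
perfectly registered rectangular specimen shows ~0 elevation, so
everything measured on a wedge specimen is attributable to the wedge
plus voxelisation). The wedge variant adds a ramp rising linearly from
zero at the central edge to `ML·tan(angle)` at the medial edge. Two
asymmetries are deliberate: the D-shape breaks the in-plane 180°
symmetry that would let registration legally swap medial and central
sides of an AP-uniform wedge, and unequal anterior (2.5 mm) vs posterior
(6 mm) medial corner radii break the AP mirror symmetry that would make
a 180° flip about the ML axis an exact registration optimum.

Defaults: ML 25 mm x AP 40 mm x 3 mm base, 0.5 mm isotropic voxels, grey
levels background 0 / spongious 120 / sclerotic 280 (optional 1-voxel
cortical shell at 200, off by default), i.i.d. Gaussian noise sd 10
(sd 15 for the standalone sclerosis slices, whose populations are
generated directly), sclerotic patches grown as contiguous blobs with
exact pixel counts. Optional tilt (rotation about AP) and a container
shell (removed by a documented crop box) exercise rotation correction
and cropping. Ground truth — voxel counts, closed-form prism volume
(with the corner/wedge interaction integrated numerically), wedge
elevations `ML·tanθ` medially and `(ML/2)·tanθ` at the split plane,
sclerotic fraction, distal slice index — is recomputable from the
`PhantomSpec` parameters in closed form.
All randomness flows from a single seed through `SeedSequence` spawning;
cohorts jitter dimensions by ±5% per specimen with deterministic
sub-seeds.

What the phantoms do *not* model: anatomic plateau shape (concavity,
eburnation, osteophytes), saw-mark roughness, partial-volume and
beam-hardening effects, formalin-related density shifts. Passing the
phantom suite therefore demonstrates the pipeline measures prescribed
geometry correctly under realistic noise — not that clinical accuracy on
real CBCT specimens matches these tolerances.

## Cohort statistics

Group comparisons use Welch's unequal-variance t-test with
Welch–Satterthwaite degrees of freedom — the safe default when group
sizes differ strongly (e.g. 8 vs 36) and the original analysis specifies
only "t-test". No multiple-testing correction is applied, matching the
per-row 0.05 convention; undefined quotients are excluded from their row
(the table records per-row n). Cohort tables report sample (ddof = 1)
standard deviations; the per-vertex distance summary inside a specimen
uses the population convention. The "all" column is the pooled mean, so
it equals the n-weighted mean of group means exactly.

## Problem sizes and determinism

The validation suite runs phantoms at 0.5 mm voxels (about 56 x 88 x 17
voxels, ~10k mesh vertices), 20-specimen cohorts, 50 random mesh pairs
for the distance oracle and 20 seeded poses for registration recovery —
sizes chosen so the whole suite and the acceptance script each complete
comfortably on a single CPU while leaving every tolerance meaningful.
Every number the pipeline produces is deterministic for fixed inputs,
configuration and seed, including the rendered PNGs.

## Known limitations

* Best-match alignment partially absorbs a full-surface wedge (~1° of
  tilt at 3°); reported elevations are best-match-frame surpluses, not
  pure cut-plane geometry.
* The quotient is undefined for specimens without medial surplus; group
  statistics on it describe the defined subset.
* The sclerosis guard is calibrated for slices of ~10^3–10^5 pixels;
  extremely small masks weaken the range-vs-scale separation.
* Only near-axis-aligned volumes are supported; oblique gantry
  acquisitions must be resampled upstream.
* Implant geometry must arrive tessellated (STL/PLY/OBJ); CAD BReps are
  out of scope, as is any non-rigid registration.
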
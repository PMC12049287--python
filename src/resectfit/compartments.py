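"""Four-compartment mismatch quantification on the registered overlay.

The implant footprint (its bounding rectangle in the ML-AP plane of the
implant frame) is quartered: anterior/posterior at the AP split and
medial/central at the ML split, giving the quadrants

* AMM - anteromedial-medial,   AMC - anteromedial-central,
* PMM - posteromedial-medial,  PMC - posteromedial-central,

an adaptation of the Krause tibial-plateau segmentation to the resected
medial plateau. Each quadrant reports the highest elevation of bone above
the implant surface, measured once in its own anterior sub-half and once
in its posterior sub-half (mirroring measurement from an anterior and a
posterior view); their sum is the quadrant total. Negative distances
(bone below the implant surface) do not count as elevation and clip to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, ValidationError
from .distmap import DistanceMap
from .volio import TriangleMesh

QUADRANTS = ("AMM", "AMC", "PMM", "PMC")
OUTSIDE = "outside"


@dataclass
class CompartmentLabeling:
    """Per-vertex quadrant label plus the split geometry that produced it."""

    labels: np.ndarray          # array of strings, one per bone vertex
    ap_split: float             # mm, implant frame (y)
    ml_split: float             # mm, implant frame (x)
    footprint: tuple            # (xmin, xmax, ymin, ymax) mm, dilated
    vertex_xy: np.ndarray       # (n, 2) projected bone vertex coords

    def counts(self) -> dict:
        return {q: int((self.labels == q).sum()) for q in (*QUADRANTS, OUTSIDE)}


@dataclass
class CompartmentReport:
    """Per-quadrant elevation maxima and the derived summary quantities."""

    anterior: dict = field(default_factory=dict)   # quadrant -> max elevation
    posterior: dict = field(default_factory=dict)
    totals: dict = field(default_factory=dict)
    total_mismatch: float | None = None
    quotient: float | None = None
    quotient_defined: bool = False
    unit: str = "voxel"

    def to_dict(self) -> dict:
        return {
            "unit": self.unit,
            "anterior": dict(self.anterior),
            "posterior": dict(self.posterior),
            "totals": dict(self.totals),
            "total_mismatch": self.total_mismatch,
            "quotient_central_medial": self.quotient,
            "quotient_defined": self.quotient_defined,
        }


def partition(bone: TriangleMesh, implant: TriangleMesh,
              split_ap: float = 0.5, split_ml: float = 0.5,
              dilate_mm: float = 1.0) -> CompartmentLabeling:
    """Label every bone vertex with its quadrant of the implant footprint.

    Both meshes must be in the implant frame (+x medial, +y anterior).
    Vertices whose ML-AP projection falls outside the footprint rectangle
    (dilated by ``dilate_mm``, nominally one voxel) are labelled
    ``outside``. Ties on a split plane go to the anterior / medial side.
    """
    if not (0.0 < split_ap < 1.0 and 0.0 < split_ml < 1.0):
        raise ValidationError("split fractions must lie in (0, 1)")
    if bone.n_vertices == 0 or implant.n_vertices == 0:
        raise DegenerateInputError("empty mesh in partition")
    fx = implant.vertices[:, 0]
    fy = implant.vertices[:, 1]
    xmin, xmax = float(fx.min()) - dilate_mm, float(fx.max()) + dilate_mm
    ymin, ymax = float(fy.min()) - dilate_mm, float(fy.max()) + dilate_mm
    # split positions as fractions measured from the posterior / central ends
    ml_split = xmin + dilate_mm + split_ml * (xmax - xmin - 2 * dilate_mm)
    ap_split = ymin + dilate_mm + split_ap * (ymax - ymin - 2 * dilate_mm)
    xy = bone.vertices[:, :2]
    inside = ((xy[:, 0] >= xmin) & (xy[:, 0] <= xmax)
              & (xy[:, 1] >= ymin) & (xy[:, 1] <= ymax))
    anterior = xy[:, 1] >= ap_split
    medial = xy[:, 0] >= ml_split      # +x is medial
    labels = np.full(len(xy), OUTSIDE, dtype=object)
    labels[inside & anterior & medial] = "AMM"
    labels[inside & anterior & ~medial] = "AMC"
    labels[inside & ~anterior & medial] = "PMM"
    labels[inside & ~anterior & ~medial] = "PMC"
    return CompartmentLabeling(labels, float(ap_split), float(ml_split),
                               (xmin, xmax, ymin, ymax), xy.copy())


def max_elevation(labeling: CompartmentLabeling, dm: DistanceMap,
                  min_normal_z: float = 0.5) -> CompartmentReport:
    """Per-quadrant maxima of positive distance, split per AP sub-half.

    Each quadrant is sub-divided at its own AP midpoint (fixed by the
    footprint geometry, not the data); the maximum positive signed
    distance is taken within each sub-half, 0 if no vertex rises above
    the implant there. Values are in the map's working unit.

    Elevation means bone *above* the implant's bearing surface: when the
    distance map carries closest-feature normals, only vertices whose
    closest implant feature faces proximally (normal z-component >=
    ``min_normal_z``, default a 60-degree cone) count — a vertex poking
    sideways past the implant rim is overhang, not elevation.
    """
    if len(labeling.labels) != len(dm.values_mm):
        raise ValidationError("labeling and distance map vertex counts differ")
    v = np.maximum(dm.values, 0.0)     # elevation only
    if dm.normal_z is not None:
        v = np.where(dm.normal_z >= min_normal_z, v, 0.0)
    y = labeling.vertex_xy[:, 1]
    _, _, ymin, ymax = labeling.footprint
    rep = CompartmentReport(unit=dm.unit)
    for q in QUADRANTS:
        sel = labeling.labels == q
        if q.startswith("A"):
            mid = (labeling.ap_split + ymax) / 2.0
        else:
            mid = (ymin + labeling.ap_split) / 2.0
        ant = sel & (y >= mid)
        post = sel & (y < mid)
        rep.anterior[q] = float(v[ant].max()) if ant.any() else 0.0
        rep.posterior[q] = float(v[post].max()) if post.any() else 0.0
    return rep


def totals_and_quotient(rep: CompartmentReport,
                        eps: float = 0.0) -> CompartmentReport:
    """Fill quadrant totals, total mismatch and the central/medial quotient.

    total(q) = anterior(q) + posterior(q); total mismatch is defined here
    as the mean of the four quadrant totals; the quotient is
    (AMC + PMC) / (AMM + PMM) on totals, flagged undefined when the
    medial denominator is <= ``eps``.
    """
    if set(rep.anterior) != set(QUADRANTS) or set(rep.posterior) != set(QUADRANTS):
        raise ValidationError("maxima must be populated for all quadrants")
    for q in QUADRANTS:
        rep.totals[q] = rep.anterior[q] + rep.posterior[q]
    rep.total_mismatch = float(np.mean([rep.totals[q] for q in QUADRANTS]))
    medial = rep.totals["AMM"] + rep.totals["PMM"]
    central = rep.totals["AMC"] + rep.totals["PMC"]
    if medial > eps:
        rep.quotient = central / medial
        rep.quotient_defined = True
    else:
        rep.quotient = None
        rep.quotient_defined = False
    return rep
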
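"""Grey-value segmentation of the resection specimen.

Emulates the interactive threshold + crop workflow digitally: a half-open
grey band ``[low, high)`` marks bone, a voxel bounding box removes the
preservation container, and the largest connected component enforces the
one-piece-specimen inclusion criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError, ValidationError
from .volio import VolumeImage, log


@dataclass
class BinaryMask:
    """Boolean voxel mask sharing geometry with its source volume."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    axes: tuple[str, str, str]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValidationError("mask must be 3D")
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.axes = tuple(self.axes)  # type: ignore[assignment]

    @classmethod
    def like(cls, vol: VolumeImage, data: np.ndarray) -> "BinaryMask":
        if data.shape != vol.data.shape:
            raise ValidationError("mask shape must match source volume")
        return cls(data, vol.spacing, vol.origin, vol.axes)

    @property
    def count(self) -> int:
        return int(self.data.sum())

    def axis_of(self, label: str) -> int:
        return self.axes.index(label)

    def as_volume(self) -> VolumeImage:
        """View as a uint8 volume, e.g. for NIfTI export."""
        return VolumeImage(self.data.astype(np.uint8), self.spacing,
                           self.origin, self.axes)


@dataclass
class BoundingBox:
    """Per-axis voxel index range, inclusive lower / exclusive upper."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        self.lower = np.asarray(self.lower, dtype=int)
        self.upper = np.asarray(self.upper, dtype=int)
        if self.lower.shape != (3,) or self.upper.shape != (3,):
            raise ValidationError("bounding box needs three lower+upper indices")
        if np.any(self.lower >= self.upper):
            raise ValidationError("bounding box lower must be < upper per axis")

    def check_within(self, shape) -> None:
        if np.any(self.lower < 0) or np.any(self.upper > np.asarray(shape)):
            raise ValidationError(f"bounding box {self.lower}..{self.upper} "
                                  f"exceeds volume shape {tuple(shape)}")

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(int(l), int(u))
                     for l, u in zip(self.lower, self.upper))  # type: ignore


def threshold_mask(vol: VolumeImage, low: float,
                   high: float = np.inf) -> BinaryMask:
    """Voxel true iff ``low <= value < high`` (half-open, stackable bands)."""
    if not low < high:
        raise ValidationError("threshold low must be < high")
    data = (vol.data >= low) & (vol.data < high)
    if not data.any():
        log.warning("threshold [%s, %s) selected no voxels", low, high)
    return BinaryMask.like(vol, data)


def otsu_threshold(vol: VolumeImage, mask: BinaryMask | None = None,
                   nbins: int = 256) -> float:
    """Between-class-variance-maximising grey threshold over the (masked) volume.

    Automated stand-in for an interactive threshold choice; the value used
    is logged so a run remains reproducible. For well-separated grey
    populations the Otsu objective is flat across the empty histogram gap
    between them; the tie is broken at the *midpoint* of the maximising
    plateau, which places the threshold mid-gap rather than at the edge
    of one population's tail.
    """
    values = vol.data[mask.data] if mask is not None else vol.data.ravel()
    if values.size == 0 or np.ptp(values) == 0:
        raise DegenerateInputError("Otsu needs >= 2 distinct grey values")
    hist, edges = np.histogram(values.astype(float), bins=nbins)
    p = hist / hist.sum()
    centers = (edges[:-1] + edges[1:]) / 2.0
    w0 = np.cumsum(p)[:-1]                  # class 0 = bins 0..i
    m0 = np.cumsum(p * centers)[:-1]
    mu = float((p * centers).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma_b = (mu * w0 - m0) ** 2 / (w0 * (1.0 - w0))
    sigma_b[(w0 <= 0) | (w0 >= 1)] = -np.inf
    best = sigma_b.max()
    plateau = np.flatnonzero(sigma_b >= best - 1e-9 * max(best, 1.0))
    # contiguous run containing the first maximiser
    first = plateau[0]
    run_end = first
    for i in plateau[1:]:
        if i == run_end + 1:
            run_end = i
        else:
            break
    t = float(edges[(first + run_end) // 2 + 1])
    log.info("otsu threshold = %.6g", t)
    return t


def crop(vol: VolumeImage, box: BoundingBox) -> VolumeImage:
    """Sub-volume with origin shifted to keep world coordinates fixed."""
    box.check_within(vol.data.shape)
    data = vol.data[box.slices()].copy()
    shift = vol.world_permutation() @ (box.lower * vol.spacing)
    return VolumeImage(data, vol.spacing.copy(), vol.origin + shift, vol.axes)


def crop_mask(mask: BinaryMask, box: BoundingBox) -> BinaryMask:
    box.check_within(mask.data.shape)
    P = VolumeImage(np.zeros((2, 2, 2)), mask.spacing, mask.origin,
                    mask.axes).world_permutation()
    shift = P @ (box.lower * mask.spacing)
    return BinaryMask(mask.data[box.slices()].copy(), mask.spacing,
                      mask.origin + shift, mask.axes)


def largest_component(mask: BinaryMask, connectivity: int = 26) -> BinaryMask:
    """Keep only the largest connected component (specimen is one piece).

    Ties are broken by the component containing the lexicographically
    smallest voxel index.
    """
    if connectivity not in (6, 26):
        raise ValidationError("connectivity must be 6 or 26")
    if not mask.data.any():
        raise DegenerateInputError("largest_component on empty mask")
    structure = ndimage.generate_binary_structure(3, 1 if connectivity == 6 else 3)
    labels, n = ndimage.label(mask.data, structure=structure)
    if n == 1:
        return BinaryMask(mask.data.copy(), mask.spacing, mask.origin, mask.axes)
    counts = np.bincount(labels.ravel())[1:]  # skip background
    best = counts.max()
    tied = np.flatnonzero(counts == best) + 1
    if len(tied) == 1:
        winner = int(tied[0])
    else:
        # lexicographic order of flattened C-order index == lexicographic
        # order of (i, j, k), so the first occurrence decides the tie
        flat = labels.ravel()
        firsts = {int(lab): int(np.argmax(flat == lab)) for lab in tied}
        winner = min(firsts, key=firsts.get)  # type: ignore[arg-type]
    return BinaryMask(labels == winner, mask.spacing, mask.origin, mask.axes)


def mask_volume(mask: BinaryMask) -> tuple[int, float]:
    """(true-voxel count, physical volume in mm^3 = count * voxel volume)."""
    count = mask.count
    return count, float(count * np.prod(mask.spacing))
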
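"""Thresholding, cropping, component selection and voxel volumes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from resectfit import segment as seg
from resectfit.errors import DegenerateInputError, ValidationError
from resectfit.segment import BinaryMask, BoundingBox
from resectfit.synth import PhantomSpec, make_resection_volume
from resectfit.volio import CANONICAL_AXES, VolumeImage


def _vol(data, spacing=(1, 1, 1)):
    return VolumeImage(np.asarray(data, dtype=float), spacing)


def test_threshold_constant_volume_all_true():
    vol = _vol(np.full((4, 4, 4), 100.0))
    assert seg.threshold_mask(vol, 50).count == 64


def test_threshold_recovers_phantom_bone_count():
    spec = PhantomSpec(noise_sd=0.0, seed=0)
    vol, truth = make_resection_volume(spec)
    mask = seg.threshold_mask(vol, 100)
    assert mask.count == truth.bone_voxel_count


def test_threshold_above_everything_warns_not_raises(caplog):
    spec = PhantomSpec(noise_sd=0.0, seed=0)
    vol, _ = make_resection_volume(spec)
    with caplog.at_level("WARNING", logger="resectfit"):
        mask = seg.threshold_mask(vol, 300)
    assert mask.count == 0
    assert any("no voxels" in r.message for r in caplog.records)


def test_threshold_half_open_interval():
    vol = _vol(np.array([[[0, 100], [200, 300]]] * 2))
    mask = seg.threshold_mask(vol, 100, 300)
    assert mask.count == 2 * 2            # 100 and 200 in each slab


@given(low1=st.floats(-50, 400), low2=st.floats(-50, 400))
@settings(deadline=None, max_examples=40)
def test_threshold_monotone_in_low(low1, low2):
    """Raising the lower bound never adds voxels."""
    rng = np.random.default_rng(11)
    vol = _vol(rng.uniform(0, 300, size=(5, 5, 5)))
    lo, hi = sorted((low1, low2))
    if lo == hi:
        return
    bigger = seg.threshold_mask(vol, lo)
    smaller = seg.threshold_mask(vol, hi)
    assert not np.any(smaller.data & ~bigger.data)


def test_otsu_separates_bimodal_phantom():
    rng = np.random.default_rng(5)
    data = np.concatenate([rng.normal(0, 10, 4000),
                           rng.normal(200, 10, 4000)]).reshape(20, 20, 20)
    t = seg.otsu_threshold(_vol(data))
    assert 50 < t < 150
    # exhaustive between-class-variance search as oracle: the returned
    # threshold must attain the maximal objective (flat across the gap)
    vals = data.ravel()
    _, edges = np.histogram(vals, bins=256)

    def objective(thr):
        lo = vals < thr
        w0, w1 = lo.sum(), (~lo).sum()
        if w0 == 0 or w1 == 0:
            return -1.0
        return w0 * w1 * (vals[lo].mean() - vals[~lo].mean()) ** 2

    best = -1.0
    for i in range(1, 256):
        best = max(best, objective(edges[i]))
    assert objective(t) >= best * (1 - 1e-9)


def test_otsu_two_voxels_and_constant():
    vol = VolumeImage(np.array([[[0.0, 10.0]] * 2] * 2), (1, 1, 1))
    t = seg.otsu_threshold(vol)
    assert 0 < t < 10
    with pytest.raises(DegenerateInputError):
        seg.otsu_threshold(_vol(np.full((3, 3, 3), 7.0)))


def test_crop_identity_and_origin_shift():
    vol = _vol(np.arange(60).reshape(3, 4, 5), spacing=(0.5, 1.0, 2.0))
    full = seg.crop(vol, BoundingBox((0, 0, 0), (3, 4, 5)))
    assert np.array_equal(full.data, vol.data)
    sub = seg.crop(vol, BoundingBox((1, 1, 2), (3, 3, 4)))
    assert sub.shape == (2, 2, 2)
    assert np.allclose(sub.origin, vol.origin + (0.5, 1.0, 4.0))
    with pytest.raises(ValidationError):
        seg.crop(vol, BoundingBox((0, 0, 0), (4, 4, 5)))


def test_nested_crops_compose():
    vol = _vol(np.arange(6 * 7 * 8).reshape(6, 7, 8))
    outer = seg.crop(vol, BoundingBox((1, 1, 1), (6, 7, 8)))
    inner_of_outer = seg.crop(outer, BoundingBox((1, 1, 1), (4, 4, 4)))
    direct = seg.crop(vol, BoundingBox((2, 2, 2), (5, 5, 5)))
    assert np.array_equal(inner_of_outer.data, direct.data)
    assert np.allclose(inner_of_outer.origin, direct.origin)


def test_crop_removes_container_shell():
    spec = PhantomSpec(container=True, noise_sd=0.0, seed=0)
    vol, truth = make_resection_volume(spec)
    n = vol.shape
    box = BoundingBox((3, 3, 3), (n[0] - 3, n[1] - 3, n[2] - 3))
    cropped = seg.crop(vol, box)
    mask = seg.threshold_mask(cropped, 100)
    assert mask.count == truth.bone_voxel_count


def test_largest_component_selection():
    data = np.zeros((20, 20, 20), dtype=bool)
    data[2:12, 2:12, 2:12] = True                      # 1000 voxels
    data[15, 15, 15:18] = True                         # 3-voxel speck
    mask = BinaryMask(data, (1, 1, 1), (0, 0, 0), CANONICAL_AXES)
    kept = seg.largest_component(mask)
    assert kept.count == 1000
    assert not kept.data[15, 15, 15]


def test_largest_component_tie_breaks_lexicographic():
    data = np.zeros((10, 10, 10), dtype=bool)
    data[1, 1, 1:6] = True
    data[8, 8, 3:8] = True
    mask = BinaryMask(data, (1, 1, 1), (0, 0, 0), CANONICAL_AXES)
    kept = seg.largest_component(mask)
    assert kept.data[1, 1, 1] and not kept.data[8, 8, 3]
    with pytest.raises(DegenerateInputError):
        seg.largest_component(BinaryMask(np.zeros((3, 3, 3), bool),
                                         (1, 1, 1), (0, 0, 0), CANONICAL_AXES))


def test_mask_volume_arithmetic_and_additivity():
    data = np.zeros((12, 12, 12), dtype=bool)
    data[:10, :10, :10] = True
    mask = BinaryMask(data, (0.5, 0.5, 0.5), (0, 0, 0), CANONICAL_AXES)
    assert seg.mask_volume(mask) == (1000, 125.0)
    empty = BinaryMask(np.zeros((3, 3, 3), bool), (1, 1, 1), (0, 0, 0),
                       CANONICAL_AXES)
    assert seg.mask_volume(empty) == (0, 0.0)
    # additivity over disjoint masks
    a = np.zeros_like(data)
    b = np.zeros_like(data)
    a[:5] = data[:5]
    b[5:] = data[5:]
    va = seg.mask_volume(BinaryMask(a, (0.5,) * 3, (0,) * 3, CANONICAL_AXES))
    vb = seg.mask_volume(BinaryMask(b, (0.5,) * 3, (0,) * 3, CANONICAL_AXES))
    assert va[0] + vb[0] == 1000 and va[1] + vb[1] == 125.0


def test_phantom_wedge_volume_close_to_analytic():
    spec = PhantomSpec(wedge_angle_deg=3.0, noise_sd=0.0, seed=0)
    vol, truth = make_resection_volume(spec)
    _, mm3 = seg.mask_volume(seg.threshold_mask(vol, 100))
    assert abs(mm3 - truth.analytic_volume_mm3) / truth.analytic_volume_mm3 < 0.03
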
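"""Shared fixtures: analytic meshes, digitised phantoms, pipeline runs."""

import numpy as np
import pytest

from resectfit.segment import BinaryMask
from resectfit.synth import PhantomSpec, make_implant_mesh, make_resection_volume
from resectfit.volio import CANONICAL_AXES, TriangleMesh


@pytest.fixture(scope="session")
def unit_cube_mesh() -> TriangleMesh:
    """Closed unit cube [0,1]^3, outward-oriented (area 6, volume 1)."""
    import trimesh
    box = trimesh.creation.box(extents=(1, 1, 1))
    return TriangleMesh(np.asarray(box.vertices) + 0.5, np.asarray(box.faces))


def digitized_sphere(radius_vox: int, voxel: float) -> BinaryMask:
    n = 2 * radius_vox + 10
    c = (n - 1) / 2.0
    x, y, z = np.mgrid[:n, :n, :n]
    m = (x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2 <= radius_vox ** 2
    return BinaryMask(m, np.full(3, voxel), np.zeros(3), CANONICAL_AXES)


@pytest.fixture(scope="session")
def sphere_mask_r15() -> BinaryMask:
    """Digitised sphere of radius 15 voxels at 1 mm isotropic spacing."""
    return digitized_sphere(15, 1.0)


@pytest.fixture(scope="session")
def default_tray() -> TriangleMesh:
    return make_implant_mesh(PhantomSpec())


def run_phantom_pipeline(spec: PhantomSpec):
    """Segment -> surface -> register -> distance -> compartments on a phantom.

    Returns (compartment report, distance map, truth, registration result).
    """
    from resectfit import compartments as comp
    from resectfit import distmap as dmap
    from resectfit import register as reg
    from resectfit import segment as seg
    from resectfit import surface as surf

    vol, truth = make_resection_volume(spec)
    tray = make_implant_mesh(spec)
    thr = seg.otsu_threshold(vol)
    mask = seg.largest_component(seg.threshold_mask(vol, thr))
    mesh = surf.extract_surface(mask)
    result = reg.icp(mesh, tray, init=reg.initial_align(mesh, tray))
    bone = reg.apply_transform(mesh, result.transform)
    dm = dmap.signed_distance(bone, tray, unit="voxel", voxel_size=spec.voxel)
    lab = comp.partition(bone, tray, dilate_mm=spec.voxel)
    report = comp.totals_and_quotient(comp.max_elevation(lab, dm))
    return report, dm, truth, result


@pytest.fixture(scope="session")
def wedge_run():
    """Full pipeline on the canonical 3-degree wedge phantom."""
    return run_phantom_pipeline(PhantomSpec(wedge_angle_deg=3.0, seed=1))


@pytest.fixture(scope="session")
def rect_run():
    """Full pipeline on the rectangular (zero-surplus) phantom."""
    return run_phantom_pipeline(PhantomSpec(wedge_angle_deg=0.0, seed=2))
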
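"""Signed distance maps vs. an exhaustive brute-force oracle; binning; views."""

import numpy as np
import pytest
import trimesh

from resectfit import distmap as dmap
from resectfit.errors import DegenerateInputError, UnitError
from resectfit.geom import MeshDistanceQuery
from resectfit.volio import TriangleMesh


def brute_force_distances(points: np.ndarray, mesh: TriangleMesh) -> np.ndarray:
    """Exhaustive min over every (point, triangle) pair, via trimesh's
    independent point-to-triangle implementation."""
    tri = mesh.vertices[mesh.faces]
    out = np.empty(len(points))
    for i, p in enumerate(points):
        cp = trimesh.triangles.closest_point(tri, np.tile(p, (len(tri), 1)))
        out[i] = np.linalg.norm(cp - p, axis=1).min()
    return out


def random_mesh(rng, n_pts=12, scale=10.0) -> TriangleMesh:
    hull = trimesh.convex.convex_hull(rng.normal(scale=scale, size=(n_pts, 3)))
    return TriangleMesh(np.asarray(hull.vertices), np.asarray(hull.faces))


@pytest.mark.parametrize("seed", range(10))
def test_closest_point_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    fixed = random_mesh(rng)
    probe = rng.normal(scale=15.0, size=(60, 3))
    d, cp, ti = MeshDistanceQuery(fixed).query(probe)
    ref = brute_force_distances(probe, fixed)
    assert np.allclose(d, ref, atol=1e-9)
    # returned closest points are consistent with the distances
    assert np.allclose(np.linalg.norm(probe - cp, axis=1), d, atol=1e-9)


def test_pruned_tree_path_matches_brute_force():
    """Meshes above the exhaustive-path cutoff go through the KD-tree
    candidate pruning; it must stay exact."""
    ico = trimesh.creation.icosphere(subdivisions=3, radius=8.0)  # 1280 faces
    mesh = TriangleMesh(np.asarray(ico.vertices), np.asarray(ico.faces))
    q = MeshDistanceQuery(mesh)
    assert q._tree is not None
    rng = np.random.default_rng(3)
    probe = rng.normal(scale=12.0, size=(100, 3))
    d, _, _ = q.query(probe)
    assert np.allclose(d, brute_force_distances(probe, mesh), atol=1e-9)


def test_identical_meshes_zero_distance(default_tray):
    dm = dmap.signed_distance(default_tray, default_tray, unit="mm")
    assert np.allclose(dm.values_mm, 0.0, atol=1e-12)


def test_parallel_plate_analytic():
    plate = TriangleMesh([[0, 0, 0], [10, 0, 0], [10, 10, 0], [0, 10, 0]],
                         [[0, 1, 2], [0, 2, 3]])
    above = TriangleMesh(np.asarray(plate.vertices) * [0.5, 0.5, 1.0]
                         + [2.5, 2.5, 2.0], plate.faces)
    dm = dmap.signed_distance(above, plate, unit="voxel", voxel_size=1.0)
    assert np.allclose(dm.values, 2.0, atol=1e-12)


def test_sign_flips_below_surface(default_tray):
    probe_above = default_tray.vertices.mean(axis=0) + [0.0, 0.0, 50.0]
    probe_inside = default_tray.vertices.mean(axis=0) + [0.0, 0.0, 1.0]
    q = MeshDistanceQuery(default_tray)
    d, _, _, normals = q.signed_query(np.vstack([probe_above, probe_inside]))
    assert d[0] > 0          # outside, above the top face
    assert d[1] < 0          # interior point
    assert normals[0, 2] > 0.99   # closest feature is the proximal face


def test_unit_conversion_voxel_vs_mm():
    dm = dmap.DistanceMap(np.array([1.0, -0.5, 3.0]), unit="voxel",
                          voxel_size=0.5)
    assert np.allclose(dm.values, [2.0, -1.0, 6.0])
    assert np.allclose(dm.in_unit("mm").values, [1.0, -0.5, 3.0])


def test_summarize_arithmetic():
    dm = dmap.DistanceMap(np.array([1.0, 3.0]), unit="mm")
    mean, sd, mx = dmap.summarize(dm)
    assert (mean, sd, mx) == (2.0, 1.0, 3.0)   # population sd convention
    zero = dmap.DistanceMap(np.zeros(5), unit="mm")
    assert dmap.summarize(zero) == (0.0, 0.0, 0.0)
    signed = dmap.DistanceMap(np.array([-4.0, 1.0]), unit="mm")
    assert dmap.summarize(signed)[2] == 1.0    # max over signed values


def test_binning_boundaries_and_conservation():
    vals = np.array([0.5, 7.5, 8.2, -0.3, 1.0, 7.999, 0.0])
    dm = dmap.DistanceMap(vals, unit="voxel", voxel_size=1.0)
    b = dmap.bin_distances(dm)
    assert b.counts["Light Blue"] == 2         # 0.5 and 0.0
    assert b.counts["Dark Blue"] == 1          # 1.0 (half-open [1,2))
    assert b.counts["Pink"] == 2               # 7.5 and 7.999
    assert b.overflow == 1 and b.negative == 1
    assert b.total() == len(vals)


def test_binning_requires_voxel_unit():
    dm = dmap.DistanceMap(np.array([1.0]), unit="mm")
    with pytest.raises(UnitError):
        dmap.bin_distances(dm)


def test_empty_distance_map_rejected():
    with pytest.raises(DegenerateInputError):
        dmap.DistanceMap(np.array([]))


def test_distance_export_roundtrip(tmp_path, default_tray):
    dm = dmap.signed_distance(default_tray, default_tray, unit="voxel",
                              voxel_size=0.5)
    csv_path = tmp_path / "d.csv"
    dmap.export_distances_csv(dm, csv_path)
    rows = csv_path.read_text().strip().splitlines()
    assert len(rows) == default_tray.n_vertices + 1
    ply_path = tmp_path / "d.ply"
    dmap.export_distances_ply(default_tray, dm, ply_path)
    text = ply_path.read_text()
    assert "property float distance" in text
    assert text.count("\n3 ") >= default_tray.n_faces - 1


def test_render_views_deterministic(tmp_path, default_tray, unit_cube_mesh):
    bone = TriangleMesh(unit_cube_mesh.vertices * 8.0 + [0, 0, 3.5],
                        unit_cube_mesh.faces)
    dm = dmap.signed_distance(bone, default_tray, unit="voxel",
                              voxel_size=1.0)
    out1 = dmap.render_views(bone, default_tray, dm, tmp_path / "a")
    out2 = dmap.render_views(bone, default_tray, dm, tmp_path / "b")
    names = sorted(p.name for p in out1)
    assert names == ["anterior.png", "lateral.png", "oblique_lateral.png",
                     "oblique_medial.png", "posterior.png", "proximal.png"]
    for p1, p2 in zip(sorted(out1), sorted(out2)):
        assert p1.read_bytes() == p2.read_bytes()


def test_render_views_rejects_mismatched_map(tmp_path, default_tray):
    dm = dmap.DistanceMap(np.zeros(3), unit="voxel")
    with pytest.raises(DegenerateInputError):
        dmap.render_views(default_tray, default_tray, dm, tmp_path)
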
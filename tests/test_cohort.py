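"""Pipeline orchestration, Welch statistics, cohort table construction."""

import json
from pathlib import Path

import numpy as np
import pytest

from resectfit import cohort as coh
from resectfit import volio
from resectfit.errors import StageError, ValidationError
from resectfit.synth import PhantomSpec, make_implant_mesh, make_resection_volume
from resectfit.volio import PipelineConfig


def welch_closed_form(a, b):
    """Textbook Welch t with Welch-Satterthwaite df, via the t CDF."""
    from scipy.stats import t as tdist
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
    return t, 2.0 * tdist.sf(abs(t), df)


def test_welch_matches_closed_form():
    rng = np.random.default_rng(8)
    for _ in range(20):
        a = rng.normal(0, 1, rng.integers(3, 30))
        b = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2),
                       rng.integers(3, 30))
        t, p = coh.welch_t(a, b)
        t0, p0 = welch_closed_form(a, b)
        assert abs(t - t0) < 1e-10
        assert abs(p - p0) < 1e-10


def test_welch_identical_groups():
    t, p = coh.welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert t == 0.0 and p == 1.0


def test_welch_separated_groups_p_to_zero():
    """As within-group spread shrinks at fixed +10 shift, p tends to 0."""
    base = np.array([1.0, 2.0, 3.0])
    ps = []
    for s in (1.0, 0.1, 0.01):
        a = base.mean() + s * (base - base.mean())
        _, p = coh.welch_t(a, a + 10.0 + np.array([1e-6, 0, -1e-6]))
        ps.append(p)
    assert ps[0] > ps[1] > ps[2]
    assert ps[2] < 1e-9


def test_welch_requires_two_per_group():
    with pytest.raises(ValidationError):
        coh.welch_t([1.0], [1.0, 2.0])


def test_implant_voxel_volume_examples(unit_cube_mesh, default_tray):
    vox, mm3 = coh.implant_voxel_volume(unit_cube_mesh, 1.0)
    assert vox == pytest.approx(1.0, abs=1e-12)
    box = make_implant_mesh(PhantomSpec(corner_radius=0.0,
                                        corner_radius_anterior=0.0))
    vox, mm3 = coh.implant_voxel_volume(box, 0.5)
    assert vox == pytest.approx(24000.0, rel=1e-9)       # 25*40*3 / 0.125
    # consistency with mesh metrics on the real tray
    from resectfit.surface import mesh_metrics
    _, vol = mesh_metrics(default_tray)
    vox, _ = coh.implant_voxel_volume(default_tray, 0.5)
    assert vox == pytest.approx(vol / 0.125, rel=1e-12)


@pytest.fixture(scope="module")
def specimen_run(tmp_path_factory):
    """One complete pipeline run on a coarse wedge phantom with sclerosis."""
    td = tmp_path_factory.mktemp("specimen")
    spec = PhantomSpec(wedge_angle_deg=3.0, sclerotic_fraction=0.15, seed=21)
    vol, truth = make_resection_volume(spec)
    tray = make_implant_mesh(spec)
    volio.write_volume(vol, td / "v.nii.gz")
    volio.write_mesh(tray, td / "t.stl")
    cfg = PipelineConfig()
    res = coh.run_specimen(td / "v.nii.gz", td / "t.stl", cfg, td / "out",
                           specimen_id="p1", group="0deg")
    return td, res, truth


def test_run_specimen_recovers_truth(specimen_run):
    _, res, truth = specimen_run
    assert abs(res.sclerosis.percentage - 100 * truth.sclerotic_fraction) < 1.5
    r = res.compartment_report
    assert r.totals["AMM"] > r.totals["AMC"]             # medial surplus
    assert r.quotient is not None and r.quotient < 1.0
    assert abs(res.volume_bone_voxels - truth.bone_voxel_count) \
        / truth.bone_voxel_count < 0.01
    assert res.volume_ratio == pytest.approx(
        res.volume_bone_voxels / res.volume_implant_voxels)


def test_run_specimen_writes_rereadable_intermediates(specimen_run):
    td, res, _ = specimen_run
    out = td / "out"
    mask = volio.read_volume(out / "mask.nii.gz")
    assert mask.data.sum() == res.volume_bone_voxels
    bone = volio.read_mesh(out / "bone_registered.stl")
    assert bone.n_faces > 0
    from resectfit.register import load_transform
    t = load_transform(out / "transform.txt")
    assert np.allclose(t.rotation.T @ t.rotation, np.eye(3), atol=1e-9)
    report = json.loads((out / "report.json").read_text())
    assert report["specimen_id"] == "p1"
    assert report["compartments"]["quotient_central_medial"] == \
        pytest.approx(res.compartment_report.quotient)
    views = sorted(p.name for p in (out / "views").glob("*.png"))
    assert len(views) == 6


def test_run_specimen_deterministic(specimen_run, tmp_path):
    td, res, _ = specimen_run
    cfg = PipelineConfig()
    res2 = coh.run_specimen(td / "v.nii.gz", td / "t.stl", cfg, tmp_path,
                            specimen_id="p1", group="0deg")
    assert res2.surface_distance_mean == res.surface_distance_mean
    assert res2.compartment_report.totals == res.compartment_report.totals
    assert res2.sclerosis.percentage == res.sclerosis.percentage
    for name in ("anterior.png", "proximal.png"):
        assert (tmp_path / "views" / name).read_bytes() \
            == (td / "out" / "views" / name).read_bytes()


def test_run_specimen_names_failing_stage(tmp_path, default_tray):
    volio.write_mesh(default_tray, tmp_path / "t.stl")
    (tmp_path / "broken.nii").write_bytes(b"garbage" * 10)
    with pytest.raises(StageError) as exc:
        coh.run_specimen(tmp_path / "broken.nii", tmp_path / "t.stl",
                         PipelineConfig(), tmp_path / "out")
    assert exc.value.stage == "segment-input"


def _fake_results(values_by_group):
    """SpecimenResult stand-ins carrying prescribed scalar metrics."""
    from resectfit.compartments import CompartmentReport, totals_and_quotient
    from resectfit.sclerosis import SclerosisResult
    out = []
    for group, rows in values_by_group.items():
        for i, v in enumerate(rows):
            rep = CompartmentReport(
                anterior={"AMM": v, "AMC": 2 * v, "PMM": v, "PMC": 2 * v},
                posterior={"AMM": v, "AMC": 2 * v, "PMM": v, "PMC": 2 * v})
            rep = totals_and_quotient(rep)
            out.append(coh.SpecimenResult(
                specimen_id=f"{group}{i}", group=group,
                surface_distance_mean=v, surface_distance_sd=0.0,
                surface_distance_max=v,
                volume_bone_voxels=1000, volume_bone_mm3=125.0,
                volume_implant_voxels=500.0, volume_implant_mm3=62.5,
                volume_ratio=2.0, compartment_report=rep,
                sclerosis=SclerosisResult(0, 100, 0.0, 1.0, 0),
                registration_rms=0.0))
    return out


def test_cohort_table_identical_groups_p_one():
    res = _fake_results({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
    table = coh.build_cohort_table(res)
    assert table.loc["surface_distance", "p"] == pytest.approx(1.0)
    assert table.loc["surface_distance", "a_sd"] == pytest.approx(1.0)


def test_cohort_table_all_column_is_weighted_group_mean():
    res = _fake_results({"a": [1.0, 2.0], "b": [4.0, 5.0, 6.0]})
    table = coh.build_cohort_table(res)
    row = table.loc["surface_distance"]
    weighted = (2 * row["a_mean"] + 3 * row["b_mean"]) / 5
    assert row["all_mean"] == pytest.approx(weighted, abs=1e-9)


def test_cohort_table_single_group_warns(caplog):
    res = _fake_results({"a": [1.0, 2.0, 3.0]})
    with caplog.at_level("WARNING", logger="resectfit"):
        table = coh.build_cohort_table(res)
    assert np.isnan(table.loc["surface_distance", "p"])
    assert any("one group" in r.message for r in caplog.records)


def test_cohort_table_constant_metric_zero_sd():
    res = _fake_results({"a": [2.0, 2.0, 2.0], "b": [2.0, 2.0]})
    table = coh.build_cohort_table(res)
    assert table.loc["surface_distance", "all_sd"] == 0.0
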
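"""Per-specimen pipeline orchestration and cohort-level reporting.

``run_specimen`` executes segment -> surface -> register -> distance map
-> compartments -> sclerosis on one volume/implant pair, writing every
intermediate (mask, meshes, transform, distances, renders, report JSON)
to a per-specimen output directory; ``build_cohort_table`` aggregates the
scalar results per group with mean +/- sd and a Welch two-sample t-test
per row (per-row 0.05 threshold, no multiplicity correction by default —
a correction can be applied downstream if desired).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import compartments as comp
from . import distmap as dmap
from . import register as reg
from . import sclerosis as scl
from . import segment as seg
from . import surface as surf
from . import volio
from .errors import DegenerateInputError, StageError, ValidationError
from .geom import MeshDistanceQuery
from .volio import PipelineConfig, TriangleMesh, VolumeImage, log


@dataclass
class SpecimenResult:
    """Scalar outcomes of one specimen, Table-2/Table-3-shaped."""

    specimen_id: str
    group: str
    surface_distance_mean: float        # mean |d|, working unit
    surface_distance_sd: float
    surface_distance_max: float
    volume_bone_voxels: int
    volume_bone_mm3: float
    volume_implant_voxels: float
    volume_implant_mm3: float
    volume_ratio: float
    compartment_report: comp.CompartmentReport
    sclerosis: scl.SclerosisResult
    registration_rms: float
    unit: str = "voxel"
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.volume_implant_voxels > 0:
            expected = self.volume_bone_voxels / self.volume_implant_voxels
            if abs(expected - self.volume_ratio) > 1e-9:
                raise ValidationError("volume ratio inconsistent")

    def scalars(self) -> dict:
        r = self.compartment_report
        return {
            "surface_distance": self.surface_distance_mean,
            "volume_bone": float(self.volume_bone_voxels),
            "volume_implant": self.volume_implant_voxels,
            "volume_ratio": self.volume_ratio,
            "total_AMM": r.totals.get("AMM", np.nan),
            "total_AMC": r.totals.get("AMC", np.nan),
            "total_PMM": r.totals.get("PMM", np.nan),
            "total_PMC": r.totals.get("PMC", np.nan),
            "total_mismatch": (r.total_mismatch
                               if r.total_mismatch is not None else np.nan),
            "quotient_central_medial": (r.quotient if r.quotient_defined
                                        else np.nan),
            "sclerosis_percent": self.sclerosis.percentage,
        }

    def to_dict(self) -> dict:
        d = {"specimen_id": self.specimen_id, "group": self.group,
             "unit": self.unit,
             "surface_distance_mean": self.surface_distance_mean,
             "surface_distance_sd": self.surface_distance_sd,
             "surface_distance_max": self.surface_distance_max,
             "volume_bone_voxels": self.volume_bone_voxels,
             "volume_bone_mm3": self.volume_bone_mm3,
             "volume_implant_voxels": self.volume_implant_voxels,
             "volume_implant_mm3": self.volume_implant_mm3,
             "volume_ratio": self.volume_ratio,
             "registration_rms_mm": self.registration_rms,
             "compartments": self.compartment_report.to_dict(),
             "sclerosis": self.sclerosis.to_dict()}
        d.update(self.extras)
        return d


def implant_voxel_volume(implant: TriangleMesh,
                         voxel_size: float) -> tuple[float, float]:
    """(enclosed volume in voxel units, in mm^3) of a closed implant mesh."""
    if voxel_size <= 0:
        raise ValidationError("voxel_size must be > 0")
    _, vol = surf.mesh_metrics(implant)
    if vol is None:
        raise DegenerateInputError("implant mesh is not closed")
    return vol / voxel_size ** 3, vol


def welch_t(group_a, group_b) -> tuple[float, float]:
    """Welch's unequal-variance t statistic and two-sided p."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs n >= 2")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    if np.isnan(t) and np.allclose(a.mean(), b.mean()):
        return 0.0, 1.0                  # two zero-variance equal groups
    return float(t), float(p)


def _stage(name):
    """Decorator-ish context: re-raise any stage failure with its name."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(name, str(exc)) from exc
            return False
    return _Ctx()


def run_specimen(volume_path, implant_path, config: PipelineConfig,
                 out_dir, specimen_id: str = "specimen",
                 group: str = "ungrouped") -> SpecimenResult:
    """Execute the full best-match pipeline on one specimen.

    Every intermediate is written under ``out_dir``; the run is
    deterministic for fixed inputs and configuration.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out_dir / "config.yaml")

    with _stage("segment-input"):
        vol = volio.read_volume(volume_path)
        implant = volio.read_mesh(implant_path, scale=config.mesh_scale)
    return _run_specimen_loaded(vol, implant, config, out_dir,
                                specimen_id, group)


def _run_specimen_loaded(vol: VolumeImage, implant: TriangleMesh,
                         config: PipelineConfig, out_dir: Path,
                         specimen_id: str, group: str) -> SpecimenResult:
    voxel_size = float(np.mean(vol.spacing))
    if np.ptp(vol.spacing) > 1e-9:
        log.warning("anisotropic spacing %s; voxel unit uses the mean",
                    vol.spacing)

    with _stage("segment"):
        if config.crop_box is not None:
            box = seg.BoundingBox(*config.crop_box)
            vol = seg.crop(vol, box)
        if config.threshold_mode == "otsu":
            thr = seg.otsu_threshold(vol)
        else:
            thr = float(config.fixed_threshold)
        mask = seg.threshold_mask(vol, thr)
        if not mask.data.any():
            raise DegenerateInputError("bone threshold selected no voxels")
        mask = seg.largest_component(mask)
        bone_voxels, bone_mm3 = seg.mask_volume(mask)
        volio.write_volume(mask.as_volume(), out_dir / "mask.nii.gz")

    with _stage("surface"):
        bone_mesh = surf.extract_surface(mask)
        if config.smoothing:
            bone_mesh = surf.smooth_mesh(bone_mesh,
                                         config.smoothing_iterations,
                                         config.smoothing_relaxation)
        volio.write_mesh(bone_mesh, out_dir / "bone.stl")

    with _stage("register"):
        init = reg.initial_align(bone_mesh, implant)
        result = reg.icp(bone_mesh, implant, init=init,
                         max_iterations=config.icp_max_iterations,
                         tol=config.icp_convergence_tol,
                         trim_fraction=config.icp_trim_fraction)
        bone_reg = reg.apply_transform(bone_mesh, result.transform)
        reg.save_transform(result.transform, out_dir / "transform.txt")
        volio.write_mesh(bone_reg, out_dir / "bone_registered.stl")

    with _stage("distmap"):
        query = MeshDistanceQuery(implant)
        dm = dmap.signed_distance(bone_reg, implant,
                                  unit=config.distance_unit,
                                  voxel_size=voxel_size, query=query)
        sd_mean, sd_sd, sd_max = dmap.summarize(dm)
        binning = dmap.bin_distances(dm.in_unit("voxel"))
        dmap.export_distances_csv(dm, out_dir / "distances.csv")
        dmap.export_distances_ply(bone_reg, dm, out_dir / "distances.ply")
        (out_dir / "binning.json").write_text(json.dumps(
            {"counts": binning.counts, "overflow": binning.overflow,
             "negative": binning.negative}, indent=2))
        if config.render:
            dmap.render_views(bone_reg, implant, dm, out_dir / "views")

    with _stage("compartments"):
        labeling = comp.partition(bone_reg, implant,
                                  split_ap=config.compartment_split_ap,
                                  split_ml=config.compartment_split_ml,
                                  dilate_mm=voxel_size)
        report = comp.max_elevation(labeling, dm)
        report = comp.totals_and_quotient(report)

    with _stage("sclerosis"):
        vol_rc, mask_rc = scl.rotation_correct(vol, mask)
        grey2d, mask2d, k = scl.most_distal_slice(
            vol_rc, mask_rc, min_area_fraction=config.slice_min_area_fraction)
        scl_result = scl.score_slice(
            grey2d, mask2d, fraction=config.sclerosis_cutoff_fraction,
            mode=config.sclerosis_cutoff_mode,
            separation_guard=config.sclerosis_separation_guard,
            slice_index=k)
        np.savetxt(out_dir / "distal_slice.csv", grey2d,
                   delimiter=",", fmt="%.3f")

    with _stage("report"):
        implant_vox, implant_mm3 = implant_voxel_volume(implant, voxel_size)
        res = SpecimenResult(
            specimen_id=specimen_id, group=group,
            surface_distance_mean=sd_mean, surface_distance_sd=sd_sd,
            surface_distance_max=sd_max,
            volume_bone_voxels=bone_voxels, volume_bone_mm3=bone_mm3,
            volume_implant_voxels=implant_vox, volume_implant_mm3=implant_mm3,
            volume_ratio=bone_voxels / implant_vox,
            compartment_report=report, sclerosis=scl_result,
            registration_rms=result.rms, unit=config.distance_unit,
            extras={"threshold_used": thr,
                    "icp_iterations": result.iterations,
                    "icp_converged": result.converged})
        (out_dir / "report.json").write_text(
            json.dumps(res.to_dict(), indent=2))
    return res


# ---------------------------------------------------------------------------
# Cohort aggregation
# ---------------------------------------------------------------------------

#: row order mirrors the published matching-parameter / variability tables
TABLE_METRICS = ("surface_distance", "volume_bone", "volume_implant",
                 "volume_ratio", "total_AMM", "total_AMC", "total_PMM",
                 "total_PMC", "total_mismatch", "quotient_central_medial",
                 "sclerosis_percent")


def build_cohort_table(results: list[SpecimenResult]) -> pd.DataFrame:
    """Per-metric rows: All / per-group mean +/- sd (sample sd) and Welch p."""
    if not results:
        raise ValidationError("no specimen results")
    groups = sorted({r.group for r in results})
    data = {g: [r.scalars() for r in results if r.group == g] for g in groups}
    single_group = len(groups) < 2
    if single_group:
        log.warning("only one group; no p-values computed")
    rows = []
    for metric in TABLE_METRICS:
        row = {"metric": metric}
        allv = np.asarray([s[metric] for g in groups for s in data[g]],
                          dtype=float)
        allv = allv[np.isfinite(allv)]
        row["all_n"] = len(allv)
        row["all_mean"] = float(allv.mean()) if len(allv) else np.nan
        row["all_sd"] = (float(allv.std(ddof=1)) if len(allv) > 1 else 0.0)
        vecs = []
        for g in groups:
            v = np.asarray([s[metric] for s in data[g]], dtype=float)
            v = v[np.isfinite(v)]
            vecs.append(v)
            row[f"{g}_n"] = len(v)
            row[f"{g}_mean"] = float(v.mean()) if len(v) else np.nan
            row[f"{g}_sd"] = float(v.std(ddof=1)) if len(v) > 1 else 0.0
        if not single_group and all(len(v) >= 2 for v in vecs[:2]):
            t, p = welch_t(vecs[0], vecs[1])
            row["t"] = t
            row["p"] = p
        else:
            row["t"] = np.nan
            row["p"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("metric")


def run_cohort(manifest_path, config: PipelineConfig,
               out_dir) -> tuple[pd.DataFrame, list[SpecimenResult]]:
    """Run every specimen in a manifest CSV (id, group, volume_path,
    implant_path) and write the cohort table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = pd.read_csv(manifest_path)
    needed = {"id", "group", "volume_path", "implant_path"}
    if not needed.issubset(manifest.columns):
        raise ValidationError(f"manifest must have columns {sorted(needed)}")
    results = []
    for _, row in manifest.iterrows():
        res = run_specimen(row["volume_path"], row["implant_path"], config,
                           out_dir / str(row["id"]),
                           specimen_id=str(row["id"]),
                           group=str(row["group"]))
        results.append(res)
    table = build_cohort_table(results)
    table.to_csv(out_dir / "cohort.csv")
    return table, results
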
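"""Volume/mesh I/O round-trips, metadata preservation and error handling."""

from pathlib import Path

import numpy as np
import pytest

from resectfit import volio
from resectfit.errors import FormatError, GeometryError, ValidationError
from resectfit.volio import PipelineConfig, TriangleMesh, VolumeImage


def _int_volume(axes=("ML", "AP", "PD")):
    rng = np.random.default_rng(3)
    data = rng.integers(0, 500, size=(6, 5, 4)).astype(np.int16)
    return VolumeImage(data, (0.5, 0.7, 1.1), (1.0, -2.0, 3.0), axes)


@pytest.mark.parametrize("suffix", [".nii", ".nii.gz", ".mha", ".mhd"])
def test_volume_roundtrip_integer_exact(tmp_path, suffix):
    vol = _int_volume()
    p = tmp_path / f"v{suffix}"
    volio.write_volume(vol, p)
    back = volio.read_volume(p)
    assert np.array_equal(back.data, vol.data)
    assert np.allclose(back.spacing, vol.spacing)
    assert np.allclose(back.origin, vol.origin)
    assert back.axes == vol.axes


@pytest.mark.parametrize("axes", [("AP", "PD", "ML"), ("PD", "ML", "AP")])
def test_axis_labels_survive_roundtrip(tmp_path, axes):
    vol = _int_volume(axes=axes)
    for suffix in (".nii.gz", ".mha"):
        p = tmp_path / f"v{suffix}"
        volio.write_volume(vol, p)
        assert volio.read_volume(p).axes == axes


def test_float_volume_roundtrip_machine_precision(tmp_path):
    rng = np.random.default_rng(4)
    vol = VolumeImage(rng.normal(size=(4, 4, 4)), (1, 1, 1))
    p = tmp_path / "f.nii.gz"
    volio.write_volume(vol, p)
    assert np.allclose(volio.read_volume(p).data, vol.data, atol=1e-12)


def test_read_volume_missing_and_unknown(tmp_path):
    with pytest.raises(FileNotFoundError):
        volio.read_volume(tmp_path / "absent.nii")
    bad = tmp_path / "x.txt"
    bad.write_text("not a volume")
    with pytest.raises(FormatError):
        volio.read_volume(bad)


def test_write_volume_unwritable_path():
    vol = _int_volume()
    with pytest.raises((OSError, FormatError)):
        volio.write_volume(vol, Path("/nonexistent-dir-xyz/v.nii"))


# --- DICOM series -----------------------------------------------------------

def _write_dicom_series(dirp: Path, nslices=3, spacing=0.2, positions=None):
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    dirp.mkdir(exist_ok=True)
    series = generate_uid(entropy_srcs=["series"])
    study = generate_uid(entropy_srcs=["study"])
    for k in range(nslices):
        ds = Dataset()
        ds.SOPClassUID = "1.2.840.10008.5.1.4.1.1.2"
        ds.SOPInstanceUID = generate_uid(entropy_srcs=[f"inst{k}"])
        ds.SeriesInstanceUID = series
        ds.StudyInstanceUID = study
        ds.Modality = "CT"
        ds.PatientName = "phantom"
        ds.PatientID = "0"
        ds.Rows = 4
        ds.Columns = 4
        ds.PixelSpacing = [spacing, spacing]
        ds.SliceThickness = spacing
        z = positions[k] if positions else k * spacing
        ds.ImagePositionPatient = [0.0, 0.0, z]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.InstanceNumber = k + 1
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = (np.arange(16).reshape(4, 4) + 10 * k) \
            .astype(np.uint16).tobytes()
        fm = FileMetaDataset()
        fm.TransferSyntaxUID = ExplicitVRLittleEndian
        fm.MediaStorageSOPClassUID = ds.SOPClassUID
        fm.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        ds.file_meta = fm
        ds.save_as(dirp / f"s{k}.dcm", enforce_file_format=True)
    _ = pydicom


def test_dicom_series_spacing(tmp_path):
    d = tmp_path / "series"
    _write_dicom_series(d, nslices=3, spacing=0.2)
    vol = volio.read_volume(d)
    assert np.allclose(vol.spacing, (0.2, 0.2, 0.2))
    assert vol.shape == (4, 4, 3)


def test_dicom_nonuniform_spacing_rejected(tmp_path):
    d = tmp_path / "bad"
    _write_dicom_series(d, nslices=4, spacing=0.2,
                        positions=[0.0, 0.2, 0.45, 0.6])
    with pytest.raises(GeometryError):
        volio.read_volume(d)


def test_empty_directory_is_format_error(tmp_path):
    d = tmp_path / "empty"
    d.mkdir()
    with pytest.raises(FormatError):
        volio.read_volume(d)


# --- meshes -----------------------------------------------------------------

def test_stl_merges_duplicate_facet_vertices(tmp_path, unit_cube_mesh):
    p = tmp_path / "cube.stl"
    volio.write_mesh(unit_cube_mesh, p)
    back = volio.read_mesh(p)
    assert back.n_vertices == 8          # 12 facets x 3 corners merged to 8
    assert back.n_faces == 12


@pytest.mark.parametrize("fmt", ["stl", "ply"])
def test_mesh_roundtrip_vertex_set(tmp_path, default_tray, fmt):
    p = tmp_path / f"tray.{fmt}"
    volio.write_mesh(default_tray, p)
    back = volio.read_mesh(p)
    a = np.asarray(sorted(map(tuple, np.round(back.vertices, 6))))
    b = np.asarray(sorted(map(tuple, np.round(default_tray.vertices, 6))))
    assert np.allclose(a, b, atol=1e-6)
    assert back.is_closed()


def test_ply_stl_cross_roundtrip(tmp_path, default_tray):
    p1 = tmp_path / "t.ply"
    volio.write_mesh(default_tray, p1)
    m1 = volio.read_mesh(p1)
    p2 = tmp_path / "t.stl"
    volio.write_mesh(m1, p2)
    m2 = volio.read_mesh(p2)
    a = np.asarray(sorted(map(tuple, np.round(m2.vertices, 6))))
    b = np.asarray(sorted(map(tuple, np.round(default_tray.vertices, 6))))
    assert np.allclose(a, b, atol=1e-6)


def test_mesh_write_is_bit_stable(tmp_path, default_tray):
    p1, p2 = tmp_path / "a.stl", tmp_path / "b.stl"
    volio.write_mesh(default_tray, p1)
    volio.write_mesh(default_tray, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_truncated_stl_is_format_error(tmp_path, unit_cube_mesh):
    p = tmp_path / "cube.stl"
    volio.write_mesh(unit_cube_mesh, p)
    (tmp_path / "trunc.stl").write_bytes(p.read_bytes()[:100])
    with pytest.raises(FormatError):
        volio.read_mesh(tmp_path / "trunc.stl")


def test_empty_mesh_rejected(tmp_path):
    mesh = TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
    with pytest.raises(ValidationError):
        volio.write_mesh(mesh, tmp_path / "e.stl")


def test_mesh_validation_invariants():
    v = np.eye(3)
    with pytest.raises(ValidationError):
        TriangleMesh(v, [[0, 1, 5]])       # index out of range
    with pytest.raises(ValidationError):
        TriangleMesh(v, [[0, 1, 1]])       # degenerate face


# --- config -----------------------------------------------------------------

def test_config_yaml_roundtrip(tmp_path):
    cfg = PipelineConfig(threshold_mode="fixed", fixed_threshold=80.0,
                         icp_trim_fraction=0.2, seed=7)
    p = tmp_path / "c.yaml"
    cfg.to_yaml(p)
    back = PipelineConfig.from_yaml(p)
    assert back == cfg


def test_config_validation():
    with pytest.raises(ValidationError):
        PipelineConfig(threshold_mode="fixed")          # missing value
    with pytest.raises(ValidationError):
        PipelineConfig(compartment_split_ap=1.5)
    with pytest.raises(ValidationError):
        PipelineConfig(icp_max_iterations=0)


def test_volume_invariants():
    with pytest.raises(ValidationError):
        VolumeImage(np.zeros((2, 2)), (1, 1, 1))        # not 3D
    with pytest.raises(ValidationError):
        VolumeImage(np.zeros((2, 2, 2)), (1, 0, 1))     # bad spacing
    with pytest.raises(ValidationError):
        VolumeImage(np.zeros((2, 2, 2)), (1, 1, 1), axes=("ML", "ML", "PD"))
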
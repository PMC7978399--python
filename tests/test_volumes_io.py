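"""Volume containers, preprocessing, and file round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sucgan import (IntensityScale, PairedSlice, VoxelVolume, compute_air_mask,
                    denormalize, extract_slices, flip_lr, normalize_to_unit)
from sucgan import io as sio
from sucgan.volumes import stack_slices


def _vol(data, **kw):
    return VoxelVolume(np.asarray(data, dtype=float), **kw)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def test_normalize_min_max_example():
    v = _vol(np.array([-1000.0, 0.0, 1000.0]).reshape(1, 1, 3))
    out, scale = normalize_to_unit(v)
    assert np.allclose(out.data.ravel(), [0.0, 0.5, 1.0])
    assert (scale.lo, scale.hi) == (-1000.0, 1000.0)
    assert out.intensity_domain == "normalized"


def test_normalize_is_identity_on_unit_range():
    v = _vol(np.array([0.0, 0.25, 1.0]).reshape(1, 1, 3))
    out, scale = normalize_to_unit(v)
    assert np.allclose(out.data, v.data)
    assert (scale.lo, scale.hi) == (0.0, 1.0)


def test_normalize_rejects_constant_volume():
    with pytest.raises(ValueError, match="constant"):
        normalize_to_unit(_vol(np.full((2, 2, 2), 7.0)))


def test_denormalize_examples():
    scale = IntensityScale(-1000.0, 1000.0)
    v = _vol(np.array([[[0.5]]]), intensity_domain="normalized")
    assert denormalize(v, scale).data.item() == pytest.approx(0.0)
    zero = _vol(np.array([[[0.0]], [[1.0]]]), intensity_domain="normalized")
    out = denormalize(zero, scale)
    assert out.data.ravel()[0] == scale.lo


@settings(max_examples=30, deadline=None)
@given(st.lists(st.floats(-2000, 3000, allow_nan=False), min_size=4, max_size=24,
                unique=True))
def test_normalize_denormalize_round_trip(values):
    data = np.asarray(values)[: 4 * (len(values) // 4)]
    if data.size < 4:
        return
    v = _vol(data.reshape(2, 2, -1))
    out, scale = normalize_to_unit(v)
    back = denormalize(out, scale)
    assert np.allclose(back.data, v.data, rtol=1e-6, atol=1e-6 * scale.width)


# ---------------------------------------------------------------------------
# air mask
# ---------------------------------------------------------------------------

def test_air_mask_recovers_phantom_body(noise_free_cohort):
    for case in noise_free_cohort:
        mask = compute_air_mask(case.ct, hu_threshold=-400.0)
        assert np.array_equal(mask, case.masks["body"])


def test_air_mask_keeps_interior_air_inside(noise_free_cohort):
    case = noise_free_cohort[0]
    air_label = case.tissue_names.index("air")
    interior_air = (case.tissue_labels == air_label) & case.masks["body"]
    assert interior_air.any(), "phantom should contain an air lumen"
    mask = compute_air_mask(case.ct)
    assert (mask & interior_air).sum() == interior_air.sum()


def test_air_mask_is_stable_under_masking(noise_free_cohort):
    case = noise_free_cohort[0]
    mask = compute_air_mask(case.ct)
    masked_ct = case.ct.with_data(np.where(mask, case.ct.data, -1000.0))
    assert np.array_equal(compute_air_mask(masked_ct), mask)


def test_air_mask_rejects_all_air_volume():
    v = _vol(np.full((8, 8, 2), -1000.0), modality="CT", intensity_domain="HU")
    with pytest.raises(ValueError, match="all air"):
        compute_air_mask(v)


# ---------------------------------------------------------------------------
# flips and slices
# ---------------------------------------------------------------------------

def test_flip_is_an_involution_and_preserves_pairing():
    rng = np.random.default_rng(0)
    s = PairedSlice("s", 0, rng.normal(size=(6, 5)), rng.normal(size=(6, 5)))
    f = flip_lr(s)
    ff = flip_lr(f)
    assert np.array_equal(ff.mr_slice, s.mr_slice)
    assert np.array_equal(ff.ct_slice, s.ct_slice)
    # voxelwise pairing is preserved under the common reflection
    assert np.array_equal(f.mr_slice, s.mr_slice[::-1, :])
    assert np.array_equal(f.ct_slice, s.ct_slice[::-1, :])
    # histograms unchanged by a permutation
    assert np.array_equal(np.sort(f.ct_slice.ravel()), np.sort(s.ct_slice.ravel()))


def test_flip_maps_right_femur_onto_left(noise_free_cohort):
    case = noise_free_cohort[0]
    k = case.n_slices // 2
    flipped_right = case.masks["femur_R"][::-1, :, k]
    assert np.array_equal(flipped_right, case.masks["femur_L"][:, :, k])


def test_slice_extraction_is_lossless(noise_free_cohort):
    case = noise_free_cohort[0]
    slices = extract_slices(case)
    assert len(slices) == case.n_slices
    assert [s.slice_index for s in slices] == list(range(case.n_slices))
    mr, ct = stack_slices(slices)
    assert np.array_equal(mr, case.mr.data)
    assert np.array_equal(ct, case.ct.data)


def test_slice_counts_match_grid(study_shaped_cohort):
    by_id = {c.subject_id: c for c in study_shaped_cohort}
    assert len(extract_slices(by_id["S01"])) == 50
    assert len(extract_slices(by_id["S04"])) == 44


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def test_nifti_round_trip_preserves_data_and_spacing(tmp_path):
    rng = np.random.default_rng(1)
    v = _vol(rng.normal(size=(8, 6, 4)), spacing_mm=(3.2, 3.2, 5.0), modality="CT",
             intensity_domain="HU")
    path = sio.write_volume(v, tmp_path / "ct.nii.gz")
    back = sio.read_volume(path, modality="CT")
    assert np.allclose(back.data, v.data)
    assert back.spacing_mm == pytest.approx((3.2, 3.2, 5.0))
    assert back.intensity_domain == "HU"


def test_read_volume_missing_path_raises(tmp_path):
    with pytest.raises(IOError):
        sio.read_volume(tmp_path / "nope.nii.gz")


def test_cohort_manifest_round_trip(tmp_path, noise_free_cohort):
    manifest = sio.write_cohort(noise_free_cohort[:2], tmp_path)
    cases = sio.read_cohort(manifest)
    assert [c.subject_id for c in cases] == [c.subject_id for c in noise_free_cohort[:2]]
    for a, b in zip(cases, noise_free_cohort[:2]):
        assert np.allclose(a.ct.data, b.ct.data)
        assert np.array_equal(a.masks["body"], b.masks["body"])


def _write_dicom_slice(path, z, rows=8, cols=6, spacing=(1.5, 2.0)):
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.Rows, ds.Columns = rows, cols
    ds.PixelSpacing = list(spacing)
    ds.ImagePositionPatient = [0.0, 0.0, float(z)]
    ds.RescaleSlope, ds.RescaleIntercept = 1.0, -1024.0
    ds.BitsAllocated, ds.BitsStored, ds.HighBit = 16, 16, 15
    ds.SamplesPerPixel, ds.PixelRepresentation = 1, 0
    ds.PhotometricInterpretation = "MONOCHROME2"
    arr = (np.arange(rows * cols, dtype=np.uint16) + int(z)).reshape(rows, cols)
    ds.PixelData = arr.tobytes()
    ds.save_as(str(path), enforce_file_format=True)
    return arr


def test_dicom_series_reader_stacks_and_rescales(tmp_path):
    d = tmp_path / "series"
    d.mkdir()
    planes = [_write_dicom_slice(d / f"s{i}.dcm", z=i * 2.5) for i in range(3)]
    v = sio.read_volume(d, format="DICOM-series", modality="CT")
    assert v.shape == (6, 8, 3)                 # (x, y, z) from (rows, cols)
    assert v.spacing_mm == pytest.approx((2.0, 1.5, 2.5))
    expected = planes[0].astype(float).T - 1024.0
    assert np.allclose(v.data[:, :, 0], expected)


def test_dicom_series_geometry_mismatch_raises(tmp_path):
    d = tmp_path / "bad"
    d.mkdir()
    _write_dicom_slice(d / "a.dcm", z=0.0, spacing=(1.5, 2.0))
    _write_dicom_slice(d / "b.dcm", z=2.5, spacing=(1.0, 2.0))
    with pytest.raises(ValueError, match="pixel spacing"):
        sio.read_volume(d, format="DICOM-series", modality="CT")


def test_label_volume_splits_into_named_masks():
    labels = np.zeros((4, 4, 2), dtype=int)
    labels[0, 0, 0] = 1
    labels[1:3, 1:3, :] = 2
    masks = sio.masks_from_label_volume(labels, {1: "GTV", 2: "bladder"})
    assert masks["GTV"].sum() == 1
    assert masks["bladder"].sum() == 8
    with pytest.raises(ValueError, match="unnamed"):
        sio.masks_from_label_volume(labels, {1: "GTV"})
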
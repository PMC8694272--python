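"""Format round trips, slice extraction, resampling and normalization."""

import numpy as np
import pytest

from fspet.data_io import (BinaryMask, ImageSlice, PairedDataset,
                           extract_sagittal_slice, load_volume,
                           normalize_intensity, read_image_png,
                           read_manifest, read_mask_png, resample_mask,
                           resample_slice, write_image_png, write_manifest,
                           write_mask_png, write_nifti)
from fspet.exceptions import (DataError, FormatError, InconsistencyError)


# ---------------------------------------------------------------------------
# domain types

def test_image_slice_rejects_bad_input():
    with pytest.raises(DataError):
        ImageSlice(np.zeros((4, 4)))          # below minimum size
    with pytest.raises(DataError):
        ImageSlice(np.full((16, 16), np.nan))  # non-finite
    with pytest.raises(DataError):
        ImageSlice(np.zeros((16, 16, 3)))      # not 2-D


def test_binary_mask_rejects_non_binary():
    with pytest.raises(DataError):
        BinaryMask(np.full((16, 16), 0.5))


def test_paired_dataset_shape_check_and_subset():
    img = ImageSlice(np.zeros((16, 16)))
    msk = BinaryMask(np.zeros((16, 16), dtype=np.uint8))
    ds = PairedDataset([(img, msk), (img, msk)], ["train", "test"])
    assert len(ds.subset("train")) == 1
    assert ds.images().shape == (2, 1, 16, 16)
    with pytest.raises(DataError):
        PairedDataset([(img, BinaryMask(np.zeros((32, 32), np.uint8)))])


# ---------------------------------------------------------------------------
# volume loading

def test_nifti_round_trip(tmp_path):
    vol = np.arange(4 * 32 * 32, dtype=np.float64).reshape(4, 32, 32)
    path = str(tmp_path / "vol.nii.gz")
    write_nifti(vol, path)
    loaded, prov = load_volume(path, format="nifti")
    assert loaded.shape == (4, 32, 32)
    np.testing.assert_array_equal(loaded, vol)
    assert "nifti" in prov


def _write_dicom(path, arr, instance, slope=1.0, intercept=0.0):
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(path, {}, file_meta=meta, preamble=b"\0" * 128)
    ds.Rows, ds.Columns = arr.shape
    ds.InstanceNumber = instance
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.RescaleSlope = slope
    ds.RescaleIntercept = intercept
    ds.PixelData = arr.astype(np.uint16).tobytes()
    ds.save_as(path, enforce_file_format=True)


def test_dicom_series_constant_value_with_rescale(tmp_path):
    d = tmp_path / "series"
    d.mkdir()
    # stored value 3 with slope 2, intercept 1 -> 7 after rescale
    for i in range(2):
        _write_dicom(str(d / f"s{i}.dcm"), np.full((16, 16), 3), i + 1,
                     slope=2.0, intercept=1.0)
    vol, prov = load_volume(str(d), format="dicom-series")
    assert vol.shape == (2, 16, 16)
    assert np.all(vol == 7.0)


def test_dicom_series_inconsistent_dims_raises(tmp_path):
    d = tmp_path / "series"
    d.mkdir()
    _write_dicom(str(d / "a.dcm"), np.zeros((16, 16)), 1)
    _write_dicom(str(d / "b.dcm"), np.zeros((32, 32)), 2)
    with pytest.raises(InconsistencyError):
        load_volume(str(d), format="dicom-series")


def test_unreadable_file_names_the_file(tmp_path):
    bad = tmp_path / "broken.nii"
    bad.write_bytes(b"not a nifti")
    with pytest.raises(FormatError, match="broken.nii"):
        load_volume(str(bad), format="nifti")


@pytest.mark.parametrize("extent,expected", [(5, 2), (4, 2)])
def test_median_slice_index(extent, expected):
    vol = np.zeros((extent, 32, 32))
    vol[expected] = 1.0
    sl = extract_sagittal_slice(vol, "median")
    assert np.all(sl.pixels == 1.0)


def test_slice_index_out_of_range():
    with pytest.raises(IndexError):
        extract_sagittal_slice(np.zeros((5, 32, 32)), 9)


# ---------------------------------------------------------------------------
# resampling

def test_resample_constant_field_invariant():
    img = ImageSlice(np.full((32, 32), 0.5))
    out = resample_slice(img, (64, 64))
    assert out.pixels.shape == (64, 64)
    np.testing.assert_allclose(out.pixels, 0.5)


def test_resample_identity_is_bitwise():
    rng = np.random.default_rng(0)
    img = ImageSlice(rng.uniform(size=(32, 32)))
    out = resample_slice(img, (32, 32))
    np.testing.assert_array_equal(out.pixels, img.pixels)


def test_resample_bilinear_rows_monotone():
    img = ImageSlice(np.tile(np.linspace(0.0, 1.0, 8), (8, 1)))
    out = resample_slice(img, (8, 16))
    for row in out.pixels:
        assert np.all(np.diff(row) >= 0)
        assert row[0] <= 0.5 <= row[-1]
    # range never exceeds input range under bilinear interpolation
    assert out.pixels.min() >= 0.0 and out.pixels.max() <= 1.0


def test_resample_rejects_small_target():
    img = ImageSlice(np.zeros((32, 32)))
    with pytest.raises(ValueError):
        resample_slice(img, (4, 4))


def test_mask_resample_stays_binary():
    rng = np.random.default_rng(1)
    mask = BinaryMask((rng.uniform(size=(16, 16)) > 0.7).astype(np.uint8))
    for target in [(32, 32), (24, 40), (8, 8)]:
        out = resample_mask(mask, target)
        assert set(np.unique(out.pixels)) <= {0, 1}


# ---------------------------------------------------------------------------
# normalization

def test_minmax_normalization_hand_example():
    img = ImageSlice(np.tile(np.array([[2.0, 4.0], [6.0, 8.0]]), (8, 8)))
    out = normalize_intensity(img, "minmax")
    np.testing.assert_allclose(
        out.pixels[:2, :2], [[0.0, 1 / 3], [2 / 3, 1.0]])


def test_constant_image_normalizes_to_zero():
    out = normalize_intensity(ImageSlice(np.full((16, 16), 3.7)), "minmax")
    assert np.all(out.pixels == 0.0)


def test_minmax_is_idempotent():
    rng = np.random.default_rng(2)
    img = ImageSlice(rng.uniform(2.0, 9.0, size=(16, 16)))
    once = normalize_intensity(img, "minmax")
    twice = normalize_intensity(once, "minmax")
    np.testing.assert_allclose(twice.pixels, once.pixels)


def test_percentile_clips_outlier():
    vals = np.linspace(0.2, 0.8, 256).reshape(16, 16).copy()
    vals[7, 7] = 1e6  # hot spot
    out = normalize_intensity(ImageSlice(vals), ("percentile", 1, 99))
    assert out.pixels[7, 7] == 1.0
    # oracle: the 99th percentile of the sorted values bounds the map
    hi = np.percentile(vals, 99)
    lo = np.percentile(vals, 1)
    expect = np.clip((vals[0, 5] - lo) / (hi - lo), 0, 1)
    np.testing.assert_allclose(out.pixels[0, 5], expect)


def test_normalize_rejects_nan():
    arr = np.zeros((16, 16))
    img = ImageSlice(arr)
    img.pixels[0, 0] = np.nan  # bypass constructor check deliberately
    with pytest.raises(DataError):
        normalize_intensity(img, "minmax")


# ---------------------------------------------------------------------------
# raster + manifest round trips

def test_png_round_trips(tmp_path):
    rng = np.random.default_rng(3)
    img = ImageSlice(np.round(rng.uniform(size=(16, 16)) * 255) / 255)
    path = str(tmp_path / "img.png")
    write_image_png(img, path)
    back = read_image_png(path)
    np.testing.assert_allclose(back.pixels, img.pixels, atol=1 / 255)
    mask = BinaryMask((rng.uniform(size=(16, 16)) > 0.5).astype(np.uint8))
    mpath = str(tmp_path / "mask.png")
    write_mask_png(mask, mpath)
    np.testing.assert_array_equal(read_mask_png(mpath).pixels, mask.pixels)


def test_manifest_round_trip(tmp_path):
    rng = np.random.default_rng(4)
    rows = []
    for i in range(3):
        img = ImageSlice(np.round(rng.uniform(size=(16, 16)) * 255) / 255)
        msk = BinaryMask((rng.uniform(size=(16, 16)) > 0.5).astype(np.uint8))
        write_image_png(img, str(tmp_path / f"i{i}.png"))
        write_mask_png(msk, str(tmp_path / f"m{i}.png"))
        rows.append({"image": f"i{i}.png", "mask": f"m{i}.png",
                     "split": "train" if i < 2 else "test"})
    write_manifest(rows, str(tmp_path / "manifest.csv"))
    ds = read_manifest(str(tmp_path / "manifest.csv"))
    assert len(ds) == 3
    assert ds.split == ["train", "train", "test"]
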
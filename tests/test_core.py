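import numpy as np
import pydicom
import pytest

from mvmar.core import ImageVolume, StructureMask, clamp_hu, read_volume, resample_crop, write_volume


class TestImageVolume:
    def test_rejects_nonpositive_spacing(self):
        with pytest.raises(ValueError, match="spacing"):
            ImageVolume(np.zeros((4, 4)), (0.0, 1.0))

    def test_rejects_unknown_modality(self):
        with pytest.raises(ValueError, match="modality"):
            ImageVolume(np.zeros((4, 4)), (1.0, 1.0), modality="mri")

    def test_hu_range_by_modality(self):
        assert ImageVolume(np.zeros((4, 4)), (1.0, 1.0), modality="ct").hu_range == (-1000, 3000)
        assert ImageVolume(np.zeros((4, 4)), (1.0, 1.0), modality="mv").hu_range == (-1000, 1400)

    def test_mask_must_be_boolean_and_aligned(self):
        vol = ImageVolume(np.zeros((4, 4)), (1.0, 1.0))
        with pytest.raises(ValueError, match="boolean"):
            StructureMask("ptv", np.zeros((4, 4), dtype=int))
        m = StructureMask("ptv", np.zeros((3, 3), dtype=bool))
        with pytest.raises(ValueError, match="shape"):
            m.check_alignment(vol)


class TestNiftiRoundTrip:
    def test_integer_hu_round_trip(self, tmp_path, rng):
        vals = rng.integers(-1000, 3000, (16, 16)).astype(float)
        vol = ImageVolume(vals, (1.0, 1.0), modality="ct")
        write_volume(vol, tmp_path / "a.nii.gz", format="nifti")
        back = read_volume(tmp_path / "a.nii.gz")
        np.testing.assert_array_equal(back.values, vals)
        assert back.spacing == vol.spacing
        assert back.modality == "ct"

    def test_all_zero_slice(self, tmp_path):
        vol = ImageVolume(np.zeros((16, 16)), (1.0, 1.0))
        write_volume(vol, tmp_path / "z.nii.gz")
        assert np.all(read_volume(tmp_path / "z.nii.gz").values == 0)

    def test_extreme_hu_survives_int16(self, tmp_path):
        vol = ImageVolume(np.full((8, 8), 3000.0), (1.0, 1.0))
        write_volume(vol, tmp_path / "m.nii.gz")
        assert read_volume(tmp_path / "m.nii.gz").values.max() == 3000

    def test_refuses_nan(self, tmp_path):
        vals = np.zeros((8, 8))
        vals[0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            write_volume(ImageVolume(vals, (1.0, 1.0)), tmp_path / "bad.nii.gz")

    def test_unsupported_format(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            write_volume(ImageVolume(np.zeros((4, 4)), (1.0, 1.0)), tmp_path / "x", format="png")


class TestDicomSeries:
    def test_round_trip_applies_rescale(self, tmp_path, rng):
        vals = rng.integers(-1000, 2000, (2, 16, 16)).astype(float)
        vol = ImageVolume(vals, (2.0, 1.0, 1.0), modality="ct")
        write_volume(vol, tmp_path / "series", format="dicom-series")
        back = read_volume(tmp_path / "series", format="dicom-series")
        np.testing.assert_array_equal(back.values, vals)
        assert back.spacing == (2.0, 1.0, 1.0)

    def test_stored_value_to_hu(self, tmp_path):
        # slope 1, intercept -1024: stored 1024 -> 0 HU
        vol = ImageVolume(np.zeros((1, 8, 8)), (1.0, 1.0, 1.0))
        write_volume(vol, tmp_path / "s", format="dicom-series")
        ds = pydicom.dcmread(str(tmp_path / "s" / "slice_0000.dcm"))
        assert float(ds.RescaleIntercept) == -1024
        assert ds.pixel_array[0, 0] == 1024
        assert read_volume(tmp_path / "s").values[0, 0, 0] == 0.0

    def test_empty_directory_errors(self, tmp_path):
        (tmp_path / "empty").mkdir()
        with pytest.raises(ValueError, match="no DICOM"):
            read_volume(tmp_path / "empty", format="dicom-series")

    def test_missing_rescale_tag_errors(self, tmp_path):
        vol = ImageVolume(np.zeros((1, 8, 8)), (1.0, 1.0, 1.0))
        write_volume(vol, tmp_path / "s", format="dicom-series")
        f = tmp_path / "s" / "slice_0000.dcm"
        ds = pydicom.dcmread(str(f))
        del ds.RescaleSlope
        ds.save_as(str(f), enforce_file_format=True)
        with pytest.raises(ValueError, match="RescaleSlope"):
            read_volume(tmp_path / "s", format="dicom-series")

    def test_missing_path_errors(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_volume(tmp_path / "nope.nii.gz")


class TestResampleCrop:
    def test_constant_image_stays_constant_inside_field(self):
        vol = ImageVolume(np.zeros((64, 64)), (1.0, 1.0))
        out = resample_crop(vol, 0.5, (64, 64))
        assert np.allclose(out.values, 0.0)
        assert out.spacing == (0.5, 0.5)

    def test_crop_larger_than_field_pads_with_air(self):
        vol = ImageVolume(np.zeros((16, 16)), (1.0, 1.0))
        out = resample_crop(vol, 1.0, (32, 32))
        assert out.values[0, 0] == -1000.0
        assert out.values[16, 16] == 0.0

    def test_downsampling_from_submillimeter_grid(self):
        # a 0.54 mm grid resampled to 1 mm: physical extent preserved, so a
        # feature spanning the field occupies ~0.54x the pixels
        n = 100
        vals = np.zeros((n, n))
        vals[:, :] = 500.0
        vol = ImageVolume(vals, (0.54, 0.54))
        out = resample_crop(vol, 1.0, (n, n))
        filled = np.count_nonzero(out.values[n // 2] > -250)
        assert abs(filled - 0.54 * n) <= 2

    def test_rejects_bad_spacing(self):
        vol = ImageVolume(np.zeros((8, 8)), (1.0, 1.0))
        with pytest.raises(ValueError, match="positive"):
            resample_crop(vol, -1.0, (8, 8))


class TestClampHu:
    @pytest.mark.parametrize(
        "modality,value,expected",
        [("mv", 2200.0, 1400.0), ("ct", 3200.0, 3000.0), ("ct", -1500.0, -1000.0), ("ct", 500.0, 500.0)],
    )
    def test_clip_rules(self, modality, value, expected):
        vol = ImageVolume(np.full((4, 4), value), (1.0, 1.0), modality=modality)
        assert clamp_hu(vol).values[0, 0] == expected

    def test_idempotent_and_monotone(self, rng):
        vals = rng.uniform(-2000, 4000, (16, 16))
        vol = ImageVolume(vals, (1.0, 1.0), modality="mv")
        once = clamp_hu(vol)
        twice = clamp_hu(once)
        np.testing.assert_array_equal(once.values, twice.values)
        # order preservation
        flat_in = vals.ravel()
        flat_out = once.values.ravel()
        order = np.argsort(flat_in)
        assert np.all(np.diff(flat_out[order]) >= 0)
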
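"""Volume I/O round-trips, SUV conversion, normalization, pairing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from petcycle import pet_io
from petcycle.pet_io import (CalibrationError, NormalizationWindow,
                             PairingError, PETVolume, SeriesError,
                             SUVCalibration, WindowError, denormalize,
                             make_pairs, normalize, read_volume, to_suv,
                             write_volume)


@pytest.fixture
def small_volume():
    rng = np.random.default_rng(0)
    return PETVolume(voxels=rng.uniform(0, 10, size=(4, 4, 4)),
                     spacing=(2.0, 2.0, 2.0), frame_duration_s=150.0,
                     calibration=SUVCalibration.from_dose_per_kg(70.0),
                     intensity_kind="suv")


@pytest.mark.parametrize("fmt", ["nifti", "dicom_series"])
def test_write_read_round_trip(tmp_path, small_volume, fmt):
    path = tmp_path / ("vol.nii.gz" if fmt == "nifti" else "series")
    write_volume(small_volume, path, format=fmt)
    back = read_volume(path, format=fmt)
    atol = 1e-5 if fmt == "nifti" else 1e-3  # DICOM stores 16-bit rescaled
    assert np.allclose(back.voxels, small_volume.voxels, atol=atol)
    assert back.spacing == pytest.approx(small_volume.spacing)
    assert back.intensity_kind == small_volume.intensity_kind
    assert back.calibration.body_weight_kg == pytest.approx(70.0)


def test_round_trip_preserves_normalized_flag(tmp_path):
    vol = PETVolume(voxels=np.zeros((2, 8, 8)) - 0.5, spacing=(2, 2, 2),
                    intensity_kind="normalized")
    write_volume(vol, tmp_path / "n.nii.gz")
    assert read_volume(tmp_path / "n.nii.gz").intensity_kind == "normalized"


def test_two_mm_spacing_round_trips(tmp_path):
    vol = PETVolume(voxels=np.ones((3, 288, 288)), spacing=(2.0, 2.0, 2.0))
    write_volume(vol, tmp_path / "v.nii.gz")
    back = read_volume(tmp_path / "v.nii.gz")
    assert back.spacing == (2.0, 2.0, 2.0)
    assert back.voxels.shape == (3, 288, 288)


def test_mixed_slice_spacing_dicom_rejected(tmp_path, small_volume):
    path = tmp_path / "series"
    write_volume(small_volume, path, format="dicom_series")
    import pydicom
    f = sorted(path.glob("*.dcm"))[2]
    ds = pydicom.dcmread(str(f))
    ds.ImagePositionPatient = [0.0, 0.0, 17.3]   # break uniform spacing
    pydicom.dcmwrite(str(f), ds, enforce_file_format=True)
    with pytest.raises(SeriesError):
        read_volume(path, format="dicom_series")


def test_missing_file_raises(tmp_path):
    with pytest.raises(FileNotFoundError):
        read_volume(tmp_path / "nope.nii.gz")


class TestSUV:
    def test_dose_per_kg_concentration_gives_unit_suv(self):
        """3.7 MBq/kg dosing diluted to 3.7 kBq/mL reads SUV 1 regardless
        of body weight."""
        for weight in (50.0, 70.0, 95.0):
            cal = SUVCalibration.from_dose_per_kg(weight)
            vol = PETVolume(voxels=np.full((1, 4, 4), 3.7),
                            spacing=(2, 2, 2),
                            intensity_kind="concentration")
            out = to_suv(vol, cal)
            assert np.allclose(out.voxels, 1.0)
            assert out.intensity_kind == "suv"

    def test_direct_formula_value(self):
        cal = SUVCalibration.from_dose_per_kg(80.0)   # 296 MBq injected
        vol = PETVolume(voxels=np.full((1, 2, 2), 7.4), spacing=(2, 2, 2),
                        intensity_kind="concentration")
        assert np.allclose(to_suv(vol, cal).voxels, 2.0)

    def test_zero_concentration_gives_zero(self):
        cal = SUVCalibration.from_dose_per_kg(60.0)
        vol = PETVolume(voxels=np.zeros((1, 2, 2)), spacing=(2, 2, 2),
                        intensity_kind="concentration")
        assert np.all(to_suv(vol, cal).voxels == 0)

    def test_missing_calibration_raises(self):
        vol = PETVolume(voxels=np.ones((1, 2, 2)), spacing=(2, 2, 2),
                        intensity_kind="concentration")
        with pytest.raises(CalibrationError):
            to_suv(vol, None)

    @given(conc=st.floats(0.1, 100), dose=st.floats(50, 500),
           weight=st.floats(40, 120))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_linear_in_concentration_inverse_in_dose(self, conc, dose,
                                                     weight):
        cal = SUVCalibration(injected_dose_MBq=dose, body_weight_kg=weight)
        img = np.full((1, 2, 2), conc)
        vol = PETVolume(voxels=img, spacing=(1, 1, 1),
                        intensity_kind="concentration")
        base = to_suv(vol, cal).voxels[0, 0, 0]
        doubled = to_suv(
            PETVolume(voxels=2 * img, spacing=(1, 1, 1),
                      intensity_kind="concentration"), cal).voxels[0, 0, 0]
        half_dose = to_suv(vol, SUVCalibration(
            injected_dose_MBq=dose / 2,
            body_weight_kg=weight)).voxels[0, 0, 0]
        assert doubled == pytest.approx(2 * base, rel=1e-5)
        assert half_dose == pytest.approx(2 * base, rel=1e-5)


class TestNormalization:
    W = NormalizationWindow(lo=0.0, hi=10.0)

    def test_endpoints_and_midpoint(self):
        img = np.array([0.0, 5.0, 10.0])
        assert normalize(img, self.W) == pytest.approx([-1.0, 0.0, 1.0])

    def test_clipping_above_window(self):
        assert normalize(np.array([[99.0]]), self.W)[0, 0] == 1.0

    def test_degenerate_window_rejected(self):
        with pytest.raises(WindowError):
            NormalizationWindow(lo=5.0, hi=5.0)

    @given(st.lists(st.floats(0.0, 10.0), min_size=1, max_size=16))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_denormalize_inverts_inside_window(self, vals):
        x = np.array(vals)
        back = denormalize(normalize(x, self.W), self.W)
        assert np.allclose(back, x, atol=1e-5)

    @given(st.lists(st.floats(-5.0, 20.0), min_size=2, max_size=16))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_normalize_is_monotone(self, vals):
        x = np.sort(np.array(vals))
        y = normalize(x, self.W)
        assert np.all(np.diff(y) >= -1e-7)


class TestPairs:
    def _vol(self, n_slices, value=1.0, side=32):
        return PETVolume(voxels=np.full((n_slices, side, side), value),
                        spacing=(2, 2, 2), intensity_kind="suv")

    def test_one_pair_per_slice(self):
        pairs = make_pairs(self._vol(10), self._vol(10),
                           NormalizationWindow(0, 10), side=32)
        assert len(pairs) == 10
        assert all(p.low_dose.shape == (32, 32) for p in pairs)

    def test_mismatched_slice_counts_rejected(self):
        with pytest.raises(PairingError):
            make_pairs(self._vol(3), self._vol(4),
                       NormalizationWindow(0, 10))

    def test_identical_volumes_give_identical_members(self):
        v = self._vol(2, value=4.2)
        pairs = make_pairs(v, v, NormalizationWindow(0, 10), side=32)
        for p in pairs:
            assert np.array_equal(p.low_dose, p.standard_dose)

    def test_resampling_288_to_256_preserves_uniform_value(self):
        v = self._vol(1, value=5.0, side=288)
        pairs = make_pairs(v, v, NormalizationWindow(0, 10), side=256)
        assert pairs[0].low_dose.shape == (256, 256)
        assert np.allclose(pairs[0].low_dose, 0.0, atol=1e-5)  # 5 -> mid
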
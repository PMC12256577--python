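"""PET volume I/O, SUV calibration, and intensity normalization.

Volumes are stored as (slice, row, col) float arrays with millimetre
spacing ``(dz, dy, dx)``.  NIfTI is the primary on-disk format (written
with nibabel; acquisition metadata goes in the header description plus a
JSON sidecar), DICOM series are supported through pydicom.  Physical
intensities are body-weight SUV or activity concentration in kBq/mL;
network I/O happens in a fixed normalized window mapped to [-1, 1] so
that denormalized outputs from different images remain on one
quantitative scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from scipy import ndimage

INTENSITY_KINDS = ("counts", "concentration", "suv", "normalized")

#: SOP class for secondary-capture storage, used for exported series
_SC_SOP = "1.2.840.10008.5.1.4.1.1.7"


class FormatError(ValueError):
    """File unreadable or not in the expected format."""


class SeriesError(FormatError):
    """Inconsistent DICOM series (orientation/spacing/shape)."""


class CalibrationError(ValueError):
    """Missing or invalid SUV calibration."""


class WindowError(ValueError):
    """Degenerate normalization window."""


class PairingError(ValueError):
    """Low-dose / standard-dose volumes cannot be paired."""


@dataclass(frozen=True)
class SUVCalibration:
    """Body-weight SUV calibration (dose decay-corrected by the scanner)."""

    injected_dose_MBq: float
    body_weight_kg: float
    dose_per_kg_MBq: float = 3.7

    def __post_init__(self):
        if min(self.injected_dose_MBq, self.body_weight_kg,
               self.dose_per_kg_MBq) <= 0:
            raise CalibrationError("calibration fields must be positive")

    @classmethod
    def from_dose_per_kg(cls, body_weight_kg: float,
                         dose_per_kg_MBq: float = 3.7) -> "SUVCalibration":
        return cls(injected_dose_MBq=dose_per_kg_MBq * body_weight_kg,
                   body_weight_kg=body_weight_kg,
                   dose_per_kg_MBq=dose_per_kg_MBq)


@dataclass(frozen=True)
class NormalizationWindow:
    """Affine window: physical value `lo` maps to -1, `hi` to +1."""

    lo: float = 0.0
    hi: float = 15.0

    def __post_init__(self):
        if not self.hi > self.lo:
            raise WindowError(f"window requires hi > lo, got {self}")


@dataclass
class PETVolume:
    """A PET image volume with geometry and calibration metadata."""

    voxels: np.ndarray                      # (n_slices, rows, cols)
    spacing: tuple[float, float, float]     # (dz, dy, dx) mm
    frame_duration_s: float = 150.0
    calibration: SUVCalibration | None = None
    intensity_kind: str = "suv"

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be 3-D (slice, row, col)")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel values must be finite")
        if self.intensity_kind not in INTENSITY_KINDS:
            raise ValueError(f"unknown intensity kind {self.intensity_kind!r}")
        if self.intensity_kind != "normalized" and self.voxels.min() < 0:
            raise ValueError("physical intensities must be nonnegative")
        if min(self.spacing) <= 0:
            raise ValueError("spacing must be strictly positive")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]


@dataclass
class ImagePair:
    """One co-registered low-dose / standard-dose slice pair, normalized."""

    low_dose: np.ndarray
    standard_dose: np.ndarray
    pair_id: str
    window: NormalizationWindow

    def __post_init__(self):
        if self.low_dose.shape != self.standard_dose.shape:
            raise PairingError("pair members must share a shape")


# ---------------------------------------------------------------------------
# SUV conversion and normalization
# ---------------------------------------------------------------------------

def to_suv(vol: PETVolume, cal: SUVCalibration | None = None) -> PETVolume:
    """Convert activity concentration (kBq/mL) to body-weight SUV.

    SUV = concentration / (injected dose / body weight), with tissue
    density taken as 1 g/mL, so kBq/mL * kg / MBq gives SUV directly.
    """
    cal = cal or vol.calibration
    if cal is None:
        raise CalibrationError("SUV conversion requires a calibration")
    if vol.intensity_kind != "concentration":
        raise CalibrationError(
            f"to_suv expects concentration input, got {vol.intensity_kind}")
    suv = vol.voxels * (cal.body_weight_kg / cal.injected_dose_MBq)
    return replace(vol, voxels=suv, calibration=cal, intensity_kind="suv")


def normalize(img: np.ndarray, w: NormalizationWindow) -> np.ndarray:
    """Map [lo, hi] affinely onto [-1, 1]; values outside are clipped."""
    img = np.asarray(img, dtype=np.float32)
    scaled = 2.0 * (img - w.lo) / (w.hi - w.lo) - 1.0
    return np.clip(scaled, -1.0, 1.0)


def denormalize(img: np.ndarray, w: NormalizationWindow) -> np.ndarray:
    """Exact inverse of :func:`normalize` on the window."""
    img = np.asarray(img, dtype=np.float32)
    return (img + 1.0) * (w.hi - w.lo) / 2.0 + w.lo


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

def _nifti_paths(path: Path) -> tuple[Path, Path]:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path, path.with_name(name[: -len(suffix)] + ".json")
    raise FormatError(f"not a NIfTI path: {path}")


def _write_nifti(vol: PETVolume, path: Path) -> None:
    path, sidecar = _nifti_paths(path)
    dz, dy, dx = vol.spacing
    affine = np.diag([dx, dy, dz, 1.0])
    img = nib.Nifti1Image(np.transpose(vol.voxels, (2, 1, 0)), affine)
    img.header.set_zooms((dx, dy, dz))
    img.header["descrip"] = f"petcycle:{vol.intensity_kind}".encode()
    nib.save(img, str(path))
    meta = {"intensity_kind": vol.intensity_kind,
            "frame_duration_s": vol.frame_duration_s}
    if vol.calibration is not None:
        meta["calibration"] = {
            "injected_dose_MBq": vol.calibration.injected_dose_MBq,
            "body_weight_kg": vol.calibration.body_weight_kg,
            "dose_per_kg_MBq": vol.calibration.dose_per_kg_MBq,
        }
    sidecar.write_text(json.dumps(meta, indent=1))


def _read_nifti(path: Path) -> PETVolume:
    path, sidecar = _nifti_paths(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:                       # nibabel raises many kinds
        raise FormatError(f"cannot read NIfTI {path}: {exc}") from exc
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim == 2:
        data = data[..., None]
    dx, dy, dz = (float(z) for z in img.header.get_zooms()[:3])
    voxels = np.transpose(data, (2, 1, 0))
    kind, frame, cal = "suv", 150.0, None
    descrip = bytes(img.header["descrip"].tobytes()).split(b"\0")[0].decode()
    if descrip.startswith("petcycle:"):
        kind = descrip.split(":", 1)[1]
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        kind = meta.get("intensity_kind", kind)
        frame = float(meta.get("frame_duration_s", frame))
        if "calibration" in meta:
            cal = SUVCalibration(**meta["calibration"])
    return PETVolume(voxels=voxels, spacing=(dz, dy, dx),
                     frame_duration_s=frame, calibration=cal,
                     intensity_kind=kind)


# ---------------------------------------------------------------------------
# DICOM series
# ---------------------------------------------------------------------------

def _write_dicom_series(vol: PETVolume, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    dz, dy, dx = vol.spacing
    series_uid = generate_uid()
    study_uid = generate_uid()
    lo = float(vol.voxels.min())
    hi = float(vol.voxels.max())
    slope = (hi - lo) / 65535.0 if hi > lo else 1.0
    for i, sl in enumerate(vol.voxels):
        ds = Dataset()
        ds.file_meta = FileMetaDataset()
        ds.file_meta.MediaStorageSOPClassUID = _SC_SOP
        ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
        ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.SOPClassUID = _SC_SOP
        ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.Modality = "PT"
        ds.SeriesDescription = f"petcycle:{vol.intensity_kind}"
        ds.InstanceNumber = i + 1
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [0.0, 0.0, float(i) * dz]
        ds.PixelSpacing = [dy, dx]
        ds.SliceThickness = dz
        ds.SpacingBetweenSlices = dz
        ds.Rows, ds.Columns = sl.shape
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.RescaleSlope = slope
        ds.RescaleIntercept = lo
        ds.ActualFrameDuration = int(vol.frame_duration_s * 1000)
        if vol.calibration is not None:
            ds.PatientWeight = vol.calibration.body_weight_kg
            rph = Dataset()
            rph.RadionuclideTotalDose = \
                vol.calibration.injected_dose_MBq * 1e6   # Bq
            ds.RadiopharmaceuticalInformationSequence = [rph]
        ds.PixelData = np.round((sl - lo) / slope).astype(np.uint16).tobytes()
        pydicom.dcmwrite(out_dir / f"slice_{i:04d}.dcm", ds,
                         enforce_file_format=True)


def _read_dicom_series(path: Path) -> PETVolume:
    files = sorted(path.glob("*.dcm"))
    if not files:
        raise FormatError(f"no DICOM files under {path}")
    datasets = [pydicom.dcmread(str(f)) for f in files]
    datasets.sort(key=lambda d: float(d.ImagePositionPatient[2]))
    first = datasets[0]
    orientation = list(first.ImageOrientationPatient)
    pixel_spacing = [float(v) for v in first.PixelSpacing]
    zs = [float(d.ImagePositionPatient[2]) for d in datasets]
    if len(zs) > 1:
        gaps = np.diff(zs)
        if np.ptp(gaps) > 1e-3 or gaps[0] <= 0:
            raise SeriesError("inconsistent slice spacing in series")
        dz = float(gaps[0])
    else:
        dz = float(getattr(first, "SliceThickness", 1.0))
    slices = []
    for d in datasets:
        if list(d.ImageOrientationPatient) != orientation:
            raise SeriesError("mixed orientation in series")
        if [float(v) for v in d.PixelSpacing] != pixel_spacing:
            raise SeriesError("mixed pixel spacing in series")
        slope = float(getattr(d, "RescaleSlope", 1.0))
        intercept = float(getattr(d, "RescaleIntercept", 0.0))
        slices.append(d.pixel_array.astype(np.float32) * slope + intercept)
    kind = "suv"
    desc = str(getattr(first, "SeriesDescription", ""))
    if desc.startswith("petcycle:"):
        kind = desc.split(":", 1)[1]
    frame = float(getattr(first, "ActualFrameDuration", 150000)) / 1000.0
    cal = None
    if hasattr(first, "PatientWeight") and \
            hasattr(first, "RadiopharmaceuticalInformationSequence"):
        dose_bq = float(first.RadiopharmaceuticalInformationSequence[0]
                        .RadionuclideTotalDose)
        weight = float(first.PatientWeight)
        cal = SUVCalibration(injected_dose_MBq=dose_bq / 1e6,
                             body_weight_kg=weight,
                             dose_per_kg_MBq=dose_bq / 1e6 / weight)
    return PETVolume(voxels=np.stack(slices),
                     spacing=(dz, pixel_spacing[0], pixel_spacing[1]),
                     frame_duration_s=frame, calibration=cal,
                     intensity_kind=kind)


# ---------------------------------------------------------------------------
# public read/write
# ---------------------------------------------------------------------------

def write_volume(vol: PETVolume, path: str | Path,
                 format: str = "nifti") -> None:
    path = Path(path)
    if format == "nifti":
        _write_nifti(vol, path)
    elif format == "dicom_series":
        _write_dicom_series(vol, path)
    else:
        raise FormatError(f"unknown format {format!r}")


def read_volume(path: str | Path, format: str = "nifti") -> PETVolume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "nifti":
        return _read_nifti(path)
    if format == "dicom_series":
        return _read_dicom_series(path)
    raise FormatError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# pairing
# ---------------------------------------------------------------------------

def resample_slice(img: np.ndarray, side: int) -> np.ndarray:
    """Bilinear resampling of a square-ish slice to side x side."""
    if img.shape == (side, side):
        return np.asarray(img, dtype=np.float32)
    zoom = (side / img.shape[0], side / img.shape[1])
    return ndimage.zoom(np.asarray(img, dtype=np.float32), zoom,
                        order=1, grid_mode=True, mode="nearest")


def make_pairs(ld_volume: PETVolume, sd_volume: PETVolume,
               w: NormalizationWindow, side: int = 256,
               id_prefix: str = "pair") -> list[ImagePair]:
    """Pair same-index axial slices of two co-registered volumes.

    Slices are bilinearly resampled to ``side x side`` (the reconstruction
    matrix, 288 in the source protocol, exceeds the network input size)
    and normalized into [-1, 1].
    """
    if ld_volume.n_slices != sd_volume.n_slices:
        raise PairingError(
            f"slice count mismatch: {ld_volume.n_slices} vs "
            f"{sd_volume.n_slices}")
    pairs = []
    for i in range(ld_volume.n_slices):
        ld = normalize(resample_slice(ld_volume.voxels[i], side), w)
        sd = normalize(resample_slice(sd_volume.voxels[i], side), w)
        pairs.append(ImagePair(low_dose=ld, standard_dose=sd,
                               pair_id=f"{id_prefix}_{i:04d}", window=w))
    return pairs
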
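"""Synthetic whole-body FDG phantoms with count-limited acquisition noise.

A phantom is a piecewise-constant activity map in SUV units — an
elliptical body (background uptake ~0.8 SUV), an elliptical liver
(mean uptake ~2.5 SUV) and one or more hot spherical lesions (peak
uptake drawn from 5-14 SUV) — convolved with a Gaussian point-spread
function.  Imaging a phantom at a given frame duration is modelled as
per-pixel Poisson counting: the expected count in a pixel is
``SUV * counts_per_suv_standard * dose_fraction``, where dose_fraction
is the frame-duration ratio relative to a standard 150 s frame (a 30 s
low-dose frame gives 0.2).  The observed counts are divided back by the
same factor, so low- and standard-dose images live on one quantitative
SUV scale and differ only in noise level.

Noise is applied in image space after the PSF, the standard desk-scale
surrogate for short-frame acquisition; true short-frame reconstructions
are noisier still (randoms grow quadratically with activity), which can
be emulated by lowering ``counts_per_suv_standard``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .pet_io import (NormalizationWindow, PETVolume, SUVCalibration,
                     write_volume)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: frame-duration ratio of a 30 s low-dose to a 150 s standard-dose frame
LOW_DOSE_FRACTION = 30.0 / 150.0


class SpecError(ValueError):
    """Invalid phantom specification."""


class ParameterError(ValueError):
    """Invalid acquisition parameter."""


@dataclass(frozen=True)
class Ellipse:
    center: tuple[float, float]       # (row, col), pixels
    semi_axes: tuple[float, float]    # (a_row, a_col), pixels

    def mask(self, size: int) -> np.ndarray:
        r, c = np.ogrid[:size, :size]
        return (((r - self.center[0]) / self.semi_axes[0]) ** 2
                + ((c - self.center[1]) / self.semi_axes[1]) ** 2) <= 1.0


@dataclass(frozen=True)
class Lesion:
    center: tuple[float, float]       # (row, col), pixels
    radius_mm: float
    suv_peak: float


@dataclass
class PhantomSpec:
    """Parametric phantom + acquisition physics description."""

    image_size: int = 256
    pixel_spacing_mm: float = 2.0
    body: Ellipse | None = None
    body_suv: float = 0.8
    liver: Ellipse | None = None
    liver_suv: float = 2.5
    lesions: list[Lesion] = field(default_factory=list)
    lesion_suv_range: tuple[float, float] = (5.0, 14.0)
    psf_fwhm_mm: float = 6.0
    counts_per_suv_standard: float = 50.0
    seed: int = 0

    def __post_init__(self):
        if self.counts_per_suv_standard <= 0:
            raise SpecError("counts_per_suv_standard must be positive")
        s = self.image_size
        if self.body is None:
            self.body = Ellipse((s / 2, s / 2), (s * 0.42, s * 0.32))
        if self.liver is None:
            self.liver = Ellipse((s * 0.40, s * 0.60), (s * 0.14, s * 0.11))
        for les in self.lesions:
            if not self._inside_body(les):
                raise SpecError(f"lesion at {les.center} outside the body")

    def _inside_body(self, les: Lesion) -> bool:
        b = self.body
        return (((les.center[0] - b.center[0]) / b.semi_axes[0]) ** 2
                + ((les.center[1] - b.center[1]) / b.semi_axes[1]) ** 2) <= 1.0


@dataclass
class ActivityMap:
    """Noise-free ground-truth SUV map of a phantom."""

    suv: np.ndarray
    spec: PhantomSpec


def random_spec(base: PhantomSpec, rng: np.random.Generator,
                n_lesions: tuple[int, int] = (1, 3)) -> PhantomSpec:
    """Draw a randomized phantom around a template: jittered organ
    geometry, lesions at random in-body positions with SUV peaks drawn
    uniformly from the template's lesion range."""
    s = base.image_size
    jitter = lambda x, frac: float(x * rng.uniform(1 - frac, 1 + frac))
    body = Ellipse((s / 2 + rng.uniform(-s * 0.02, s * 0.02),
                    s / 2 + rng.uniform(-s * 0.02, s * 0.02)),
                   (jitter(s * 0.42, 0.08), jitter(s * 0.32, 0.08)))
    liver = Ellipse((jitter(s * 0.40, 0.06), jitter(s * 0.60, 0.06)),
                    (jitter(s * 0.14, 0.15), jitter(s * 0.11, 0.15)))
    lesions = []
    k = int(rng.integers(n_lesions[0], n_lesions[1] + 1))
    while len(lesions) < k:
        # rejection-sample centers well inside the body ellipse
        t = rng.uniform(0, 2 * np.pi)
        rad = np.sqrt(rng.uniform()) * 0.75
        center = (body.center[0] + rad * body.semi_axes[0] * np.sin(t),
                  body.center[1] + rad * body.semi_axes[1] * np.cos(t))
        lesions.append(Lesion(
            center=center,
            radius_mm=float(rng.uniform(6.0, 12.0)),
            suv_peak=float(rng.uniform(*base.lesion_suv_range))))
    return PhantomSpec(
        image_size=s, pixel_spacing_mm=base.pixel_spacing_mm,
        body=body, body_suv=jitter(base.body_suv, 0.1),
        liver=liver, liver_suv=jitter(base.liver_suv, 0.1),
        lesions=lesions, lesion_suv_range=base.lesion_suv_range,
        psf_fwhm_mm=base.psf_fwhm_mm,
        counts_per_suv_standard=base.counts_per_suv_standard,
        seed=base.seed)


def sample_phantom(spec: PhantomSpec, seed: int | None = None) -> ActivityMap:
    """Render the piecewise-constant SUV map and blur it with the PSF.

    Deterministic given (spec, seed); the seed only matters when organ
    interiors get mild texture in future variants, and is accepted for
    interface stability.
    """
    del seed  # rendering is a deterministic function of the spec
    s = spec.image_size
    suv = np.zeros((s, s), dtype=np.float64)
    suv[spec.body.mask(s)] = spec.body_suv
    liver_mask = spec.liver.mask(s) & spec.body.mask(s)
    suv[liver_mask] = spec.liver_suv
    r, c = np.ogrid[:s, :s]
    for les in spec.lesions:
        radius_px = les.radius_mm / spec.pixel_spacing_mm
        mask = ((r - les.center[0]) ** 2 + (c - les.center[1]) ** 2
                <= radius_px ** 2)
        suv[mask] = les.suv_peak
    sigma_px = spec.psf_fwhm_mm * FWHM_TO_SIGMA / spec.pixel_spacing_mm
    if sigma_px > 0:
        suv = ndimage.gaussian_filter(suv, sigma_px)
    return ActivityMap(suv=suv.astype(np.float32), spec=spec)


def lesion_masks(act: ActivityMap) -> np.ndarray:
    """Integer label map of the phantom's lesions (1..n, 0 = elsewhere)."""
    s = act.spec.image_size
    labels = np.zeros((s, s), dtype=np.int16)
    r, c = np.ogrid[:s, :s]
    for i, les in enumerate(act.spec.lesions, start=1):
        radius_px = les.radius_mm / act.spec.pixel_spacing_mm
        mask = ((r - les.center[0]) ** 2 + (c - les.center[1]) ** 2
                <= radius_px ** 2)
        labels[mask] = i
    return labels


def simulate_frame(act: ActivityMap, dose_fraction: float,
                   seed: int | np.random.Generator = 0
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one acquisition frame.

    Returns ``(counts, suv_image)``: per-pixel Poisson counts with mean
    ``suv * counts_per_suv_standard * dose_fraction``, and the counts
    scaled back to SUV so frames of different durations are directly
    comparable.
    """
    if not 0 < dose_fraction <= 1:
        raise ParameterError("dose_fraction must be in (0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    scale = act.spec.counts_per_suv_standard * dose_fraction
    lam = act.suv.astype(np.float64) * scale
    counts = rng.poisson(lam).astype(np.float64)
    return counts, (counts / scale).astype(np.float32)


def _split_counts(n: int, fractions: tuple[float, float, float]
                  ) -> tuple[int, int, int]:
    """Largest-remainder apportioning of n items to (train, val, test)."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ParameterError("split fractions must sum to 1")
    raw = [f * n for f in fractions]
    base = [int(np.floor(x)) for x in raw]
    rem = n - sum(base)
    order = np.argsort([b - x for b, x in zip(base, raw)])  # most owed first
    for i in range(rem):
        base[order[i]] += 1
    return tuple(base)


def generate_dataset(spec_template: PhantomSpec, n_phantoms: int,
                     slices_per_phantom: int, out_dir: str | Path,
                     seed: int = 0,
                     dose_fraction: float = LOW_DOSE_FRACTION,
                     split: tuple[float, float, float] = (0.81, 0.14, 0.05),
                     window: NormalizationWindow | None = None) -> Path:
    """Write a paired LD/SD dataset plus manifest and return the manifest path.

    Each phantom contributes ``slices_per_phantom`` pairs: the activity
    map is shared within a phantom and every slice gets fresh Poisson
    noise at both frame durations.  Files written per slice: low-dose,
    standard-dose and ground-truth SUV images (NIfTI) and a lesion label
    map.  The manifest TSV columns are pair_id, split, ld_path, sd_path,
    truth_path, mask_path, slice_index.
    """
    if n_phantoms < 1:
        raise ParameterError("n_phantoms must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    window = window or NormalizationWindow()
    master = np.random.SeedSequence(seed)
    phantom_seeds = master.spawn(n_phantoms)
    cal = SUVCalibration.from_dose_per_kg(body_weight_kg=70.0)
    dz = spec_template.pixel_spacing_mm

    rows = []
    n_total = n_phantoms * slices_per_phantom
    n_train, n_val, n_test = _split_counts(n_total, split)
    split_names = ["train"] * n_train + ["val"] * n_val + ["test"] * n_test
    idx = 0
    for p, pseed in enumerate(phantom_seeds):
        rng = np.random.default_rng(pseed)
        spec = random_spec(spec_template, rng)
        act = sample_phantom(spec)
        labels = lesion_masks(act)
        mask_path = out_dir / f"phantom{p:03d}_mask.nii.gz"
        _save_slice(labels.astype(np.float32), spec, mask_path, "suv",
                    cal, 0.0)
        truth_path = out_dir / f"phantom{p:03d}_truth.nii.gz"
        _save_slice(act.suv, spec, truth_path, "suv", cal, 0.0)
        for s in range(slices_per_phantom):
            _, ld = simulate_frame(act, dose_fraction, rng)
            _, sd = simulate_frame(act, 1.0, rng)
            pair_id = f"p{p:03d}s{s:03d}"
            ld_path = out_dir / f"{pair_id}_ld.nii.gz"
            sd_path = out_dir / f"{pair_id}_sd.nii.gz"
            _save_slice(ld, spec, ld_path, "suv", cal, 150.0 * dose_fraction)
            _save_slice(sd, spec, sd_path, "suv", cal, 150.0)
            rows.append({
                "pair_id": pair_id, "split": split_names[idx],
                "ld_path": ld_path.name, "sd_path": sd_path.name,
                "truth_path": truth_path.name, "mask_path": mask_path.name,
                "slice_index": s,
            })
            idx += 1

    manifest = out_dir / "manifest.tsv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]), delimiter="\t")
        writer.writeheader()
        writer.writerows(rows)
    meta = out_dir / "dataset.json"
    meta.write_text(_dataset_meta(spec_template, n_phantoms,
                                  slices_per_phantom, seed, dose_fraction,
                                  split, window))
    return manifest


def _save_slice(img: np.ndarray, spec: PhantomSpec, path: Path,
                kind: str, cal: SUVCalibration, frame_s: float) -> None:
    vol = PETVolume(voxels=img[None], spacing=(spec.pixel_spacing_mm,) * 3,
                    frame_duration_s=frame_s or 150.0, calibration=cal,
                    intensity_kind=kind)
    write_volume(vol, path, format="nifti")


def _dataset_meta(spec, n_phantoms, slices, seed, dose_fraction, split,
                  window) -> str:
    import json
    d = asdict(spec)
    d["body"] = asdict(spec.body)
    d["liver"] = asdict(spec.liver)
    d["lesions"] = [asdict(l) for l in spec.lesions]
    return json.dumps({
        "spec_template": d, "n_phantoms": n_phantoms,
        "slices_per_phantom": slices, "seed": seed,
        "dose_fraction": dose_fraction, "split": list(split),
        "window": {"lo": window.lo, "hi": window.hi},
    }, indent=1)
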
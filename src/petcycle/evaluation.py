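"""Objective image-quality and SUV evaluation.

PSNR is computed as ``20 log10(MAX / sqrt(MSE))`` with MAX the peak
intensity of the reference (standard-dose / ground-truth) image, so it
is invariant to a common rescaling of both images.  SSIM follows the
standard luminance x contrast-structure product over Gaussian sliding
windows (11x11, sigma 1.5, k1 = 0.01, k2 = 0.03), with the dynamic
range taken from the reference image's peak by default, matching the
PSNR convention.  ROI statistics (SUVmax / SUVmean / SD) are reported
for circular lesion regions of a fixed physical area (3 cm^2 by
default) and aggregated in the mean +/- range convention
(range = max - min).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage


class MaskError(ValueError):
    pass


class GeometryError(ValueError):
    pass


class EvaluationDataError(ValueError):
    pass


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def psnr(reference: np.ndarray, test: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB; +inf when the images coincide."""
    reference = np.asarray(reference, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if reference.shape != test.shape:
        raise ValueError("psnr requires equal shapes")
    mse = float(np.mean((reference - test) ** 2))
    if mse == 0.0:
        return math.inf
    peak = float(reference.max())
    return 20.0 * math.log10(peak / math.sqrt(mse))


def ssim(reference: np.ndarray, test: np.ndarray, window_size: int = 11,
         sigma: float = 1.5, k1: float = 0.01, k2: float = 0.03,
         dynamic_range: float | None = None) -> float:
    """Mean structural similarity over Gaussian-weighted windows."""
    x = np.asarray(reference, dtype=np.float64)
    y = np.asarray(test, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("ssim requires equal shapes")
    if window_size > min(x.shape):
        raise ValueError("window larger than image")
    if dynamic_range is None:
        dynamic_range = float(x.max())
    c1 = (k1 * dynamic_range) ** 2
    c2 = (k2 * dynamic_range) ** 2
    radius = (window_size - 1) // 2

    def filt(img):
        return ndimage.gaussian_filter(img, sigma, radius=radius)

    mu_x, mu_y = filt(x), filt(y)
    sxx = filt(x * x) - mu_x * mu_x
    syy = filt(y * y) - mu_y * mu_y
    sxy = filt(x * y) - mu_x * mu_y
    num = (2 * mu_x * mu_y + c1) * (2 * sxy + c2)
    den = (mu_x ** 2 + mu_y ** 2 + c1) * (sxx + syy + c2)
    ssim_map = num / den
    if radius:                      # exclude edge windows, as is customary
        ssim_map = ssim_map[radius:-radius, radius:-radius]
    return float(ssim_map.mean())


# ---------------------------------------------------------------------------
# ROI analysis
# ---------------------------------------------------------------------------

@dataclass
class ROIMask:
    mask: np.ndarray                 # boolean
    label: str = "lesion"            # lesion | liver | other
    area_mm2: float = 300.0

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise MaskError("ROI mask is empty")


def make_circular_roi(center: tuple[float, float], area_mm2: float,
                      spacing: tuple[float, float],
                      shape: tuple[int, int],
                      label: str = "lesion") -> ROIMask:
    """Pixelated disk of the requested physical area around `center`.

    The radius follows from area = pi r^2; the pixelated disk's area
    matches the request to within about one pixel area.
    """
    dy, dx = spacing
    radius_mm = math.sqrt(area_mm2 / math.pi)
    if (center[0] - radius_mm / dy < -0.5
            or center[0] + radius_mm / dy > shape[0] - 0.5
            or center[1] - radius_mm / dx < -0.5
            or center[1] + radius_mm / dx > shape[1] - 0.5):
        raise GeometryError("ROI does not fit inside the image")
    # take exactly the n nearest pixel centers, n = area / pixel area,
    # so the pixelated area matches the request to within one pixel
    n_pixels = max(1, round(area_mm2 / (dy * dx)))
    r, c = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]),
                       indexing="ij")
    dist2 = (((r - center[0]) * dy) ** 2
             + ((c - center[1]) * dx) ** 2).reshape(-1)
    chosen = np.argsort(dist2, kind="stable")[:n_pixels]
    mask = np.zeros(shape[0] * shape[1], dtype=bool)
    mask[chosen] = True
    return ROIMask(mask=mask.reshape(shape), label=label, area_mm2=area_mm2)


def roi_stats(img_suv: np.ndarray, roi: ROIMask
              ) -> tuple[float, float, float]:
    """(SUVmax, SUVmean, population SD) within the ROI."""
    img_suv = np.asarray(img_suv, dtype=np.float64)
    if img_suv.shape != roi.mask.shape:
        raise MaskError("image / mask shape mismatch")
    vals = img_suv[roi.mask]
    return float(vals.max()), float(vals.mean()), float(vals.std(ddof=0))


def aggregate(values) -> tuple[float, float]:
    """(mean, range) with range = max - min, the table convention."""
    vals = [float(v) for v in values]
    if not vals:
        raise ValueError("aggregate of empty sequence")
    return float(np.mean(vals)), float(np.max(vals) - np.min(vals))


# ---------------------------------------------------------------------------
# model evaluation over a dataset manifest
# ---------------------------------------------------------------------------

@dataclass
class MetricReport:
    """Per-image metric rows plus mean +/- range aggregates."""

    rows: list[dict] = field(default_factory=list)
    roi_rows: list[dict] = field(default_factory=list)
    aggregates: dict = field(default_factory=dict)

    def aggregate_column(self, col: str) -> tuple[float, float]:
        vals = [row[col] for row in self.rows if math.isfinite(row[col])]
        return aggregate(vals)

    def finalize(self) -> None:
        cols = [c for c in self.rows[0] if c != "pair_id"]
        for col in cols:
            mean, rng = self.aggregate_column(col)
            self.aggregates[col] = {"mean": mean, "range": rng}

    def write_tsv(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(self.rows[0]),
                                    delimiter="\t")
            writer.writeheader()
            writer.writerows(self.rows)
        if self.roi_rows:
            roi_path = path.with_name(path.stem + "_roi.tsv")
            with open(roi_path, "w", newline="") as fh:
                writer = csv.DictWriter(fh, fieldnames=list(self.roi_rows[0]),
                                        delimiter="\t")
                writer.writeheader()
                writer.writerows(self.roi_rows)


def save_comparison_panel(low_dose: np.ndarray, denoised: np.ndarray,
                          reference: np.ndarray, path: str | Path,
                          vmax: float | None = None) -> None:
    """Side-by-side low-dose / denoised / reference panel as PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vmax = vmax or float(reference.max())
    fig, axes = plt.subplots(1, 3, figsize=(9, 3.2))
    for ax, img, title in zip(axes, (low_dose, denoised, reference),
                              ("low-dose", "denoised", "reference")):
        ax.imshow(img, cmap="gray_r", vmin=0, vmax=vmax)
        ax.set_title(title)
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def read_manifest(manifest_path: str | Path,
                  split: str | None = None) -> list[dict]:
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        rows = list(csv.DictReader(fh, delimiter="\t"))
    if split is not None:
        rows = [r for r in rows if r["split"] == split]
    if not rows:
        raise EvaluationDataError(
            f"manifest {manifest_path} has no rows"
            + (f" for split {split!r}" if split else ""))
    return rows


def evaluate_pairs(entries: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
                   ids: list[str]) -> MetricReport:
    """Metric rows for (reference, low_dose, denoised) image triples."""
    report = MetricReport()
    for pair_id, (ref, ld, dn) in zip(ids, entries):
        report.rows.append({
            "pair_id": pair_id,
            "psnr_ld": psnr(ref, ld), "ssim_ld": ssim(ref, ld),
            "psnr_denoised": psnr(ref, dn), "ssim_denoised": ssim(ref, dn),
        })
    report.finalize()
    return report


def evaluate_model(checkpoint_path: str | Path, manifest_path: str | Path,
                   split: str = "test", reference: str = "standard_dose",
                   roi_area_mm2: float = 300.0,
                   with_roi: bool = True,
                   panel_dir: str | Path | None = None,
                   max_panels: int = 4) -> MetricReport:
    """Evaluate a trained denoiser over a dataset split.

    For every pair the low-dose baseline and the denoised image are
    scored against the chosen reference ("standard_dose" or "truth").
    When lesion masks are present, SUV statistics are computed inside
    fixed-area disks centred on each lesion centroid, on the low-dose,
    denoised and reference images.
    """
    from . import training  # deferred: training pulls in the network stack
    from .pet_io import read_volume

    rows = read_manifest(manifest_path, split)
    base = Path(manifest_path).parent
    model = training.load_checkpoint(checkpoint_path)

    if panel_dir is not None:
        panel_dir = Path(panel_dir)
        panel_dir.mkdir(parents=True, exist_ok=True)
    report = MetricReport()
    for row in rows:
        ld_vol = read_volume(base / row["ld_path"])
        sd_vol = read_volume(base / row["sd_path"])
        ref_vol = read_volume(base / row["truth_path"]) \
            if reference == "truth" else sd_vol
        dn_vol = training.denoise(model, ld_vol)
        ref = ref_vol.voxels[0]
        ld = ld_vol.voxels[0]
        dn = dn_vol.voxels[0]
        report.rows.append({
            "pair_id": row["pair_id"],
            "psnr_ld": psnr(ref, ld), "ssim_ld": ssim(ref, ld),
            "psnr_denoised": psnr(ref, dn), "ssim_denoised": ssim(ref, dn),
        })
        if panel_dir is not None and len(report.rows) <= max_panels:
            save_comparison_panel(
                ld, dn, ref, panel_dir / f"{row['pair_id']}.png")
        if with_roi and row.get("mask_path"):
            labels = read_volume(base / row["mask_path"]).voxels[0]
            spacing = ld_vol.spacing[1:]
            for lab in np.unique(labels[labels > 0]):
                centroid = ndimage.center_of_mass(labels == lab)
                try:
                    roi = make_circular_roi(centroid, roi_area_mm2,
                                            spacing, ld.shape)
                except GeometryError:
                    continue
                for name, img in (("low_dose", ld), ("denoised", dn),
                                  ("reference", ref)):
                    mx, mean, sd = roi_stats(img, roi)
                    report.roi_rows.append({
                        "pair_id": row["pair_id"], "lesion": int(lab),
                        "image": name, "suv_max": mx, "suv_mean": mean,
                        "suv_sd": sd,
                    })
    report.finalize()
    return report
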
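"""Image-quality indices: PSNR, global SSIM, NMSE, CNR/RCNR, difference maps.

Conventions follow the restoration literature this package implements:

* PSNR = 10 log10(peak^2 / MSE) in dB, with peak = 2^n - 1 for n-bit images
  or the ground-truth data range for normalized floats.
* SSIM is computed from *global* image statistics (whole-image means,
  variances, covariance) with additive constants c1 = 0.01, c2 = 0.03 — not
  the conventional windowed SSIM with c = (kL)^2. A windowed variant
  (scikit-image) is available behind ``windowed=True`` for comparability.
* NMSE = sum((x - y)^2) / sum(y^2).
* CNR = (mean_ROI - mean_background) / mean_ROI — a mean-normalized contrast,
  not the conventional noise-SD-normalized CNR; RCNR is the ratio of the CNR
  of the compared image to that of the ground truth (1 means contrast is
  preserved).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ImageGrid, Modality

__all__ = [
    "MetricConfig",
    "ROISpec",
    "MetricsReport",
    "psnr",
    "ssim_global",
    "nmse",
    "cnr",
    "rcnr",
    "relative_difference_map",
    "batch_report",
]


@dataclass(frozen=True)
class MetricConfig:
    """PSNR peak definition and SSIM constants.

    ``bit_depth`` = n sets peak = 2^n - 1 (use 8 for byte-scaled data);
    None derives the peak from the ground-truth data range, appropriate for
    normalized floats. Identical images report ``inf_sentinel`` dB.
    """

    bit_depth: int | None = None
    c1: float = 0.01
    c2: float = 0.03
    inf_sentinel: float = math.inf

    def __post_init__(self):
        if self.bit_depth is not None and self.bit_depth < 1:
            raise ValueError("bit_depth must be >= 1")
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("SSIM constants must be positive")


@dataclass
class ROISpec:
    """Named ROI / background masks for contrast measurements."""

    roi_mask: np.ndarray
    background_mask: np.ndarray
    roi_name: str = "lesion"
    background_name: str = "background"

    def __post_init__(self):
        self.roi_mask = np.asarray(self.roi_mask, dtype=bool)
        self.background_mask = np.asarray(self.background_mask, dtype=bool)
        if self.roi_mask.shape != self.background_mask.shape:
            raise ValueError("ROI and background masks must share a shape")
        if not self.roi_mask.any() or not self.background_mask.any():
            raise ValueError("ROI and background masks must be non-empty")
        if (self.roi_mask & self.background_mask).any():
            raise ValueError("ROI and background masks must be disjoint")


def _pix(x) -> np.ndarray:
    return x.pixels if isinstance(x, ImageGrid) else np.asarray(x, dtype=np.float64)


def _check_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    xa, ya = _pix(x), _pix(y)
    if xa.shape != ya.shape:
        raise ValueError(f"shape mismatch: {xa.shape} vs {ya.shape}")
    return xa, ya


def psnr(x, y, cfg: MetricConfig = MetricConfig()) -> float:
    """Peak signal-to-noise ratio of x against ground truth y, in dB."""
    xa, ya = _check_pair(x, y)
    mse = float(np.mean((xa - ya) ** 2))
    if mse == 0.0:
        return cfg.inf_sentinel
    if cfg.bit_depth is not None:
        peak = 2.0**cfg.bit_depth - 1.0
    else:
        peak = float(ya.max() - ya.min())
        if peak <= 0:
            raise ValueError("ground truth has zero data range; set bit_depth")
    return 10.0 * math.log10(peak**2 / mse)


def ssim_global(x, y, cfg: MetricConfig = MetricConfig(), windowed: bool = False) -> float:
    """Structural similarity from global statistics (default) or windowed."""
    xa, ya = _check_pair(x, y)
    if windowed:
        from skimage.metrics import structural_similarity

        rng = float(max(xa.max(), ya.max()) - min(xa.min(), ya.min()))
        return float(structural_similarity(xa, ya, data_range=rng if rng > 0 else 1.0))
    mx, my = xa.mean(), ya.mean()
    dx, dy = xa - mx, ya - my
    vx = np.mean(dx**2)
    vy = np.mean(dy**2)
    cov = np.mean(dx * dy)
    num = (2.0 * mx * my + cfg.c1) * (2.0 * cov + cfg.c2)
    den = (mx * mx + my * my + cfg.c1) * (vx + vy + cfg.c2)
    return float(num / den)


def nmse(x, y) -> float:
    """Normalized MSE: summed squared error over summed squared truth."""
    xa, ya = _check_pair(x, y)
    denom = float(np.sum(ya**2))
    if denom == 0.0:
        raise ValueError("NMSE undefined: ground truth is all zeros")
    return float(np.sum((xa - ya) ** 2)) / denom


def cnr(img, roi: ROISpec) -> float:
    """Mean-normalized ROI contrast: (mean_ROI - mean_bg) / mean_ROI."""
    px = _pix(img)
    if px.shape != roi.roi_mask.shape:
        raise ValueError("mask shape does not match image")
    x_roi = float(px[roi.roi_mask].mean())
    x_bg = float(px[roi.background_mask].mean())
    if x_roi == 0.0:
        raise ValueError("CNR undefined: ROI mean is zero")
    return (x_roi - x_bg) / x_roi


def rcnr(x, y, roi: ROISpec) -> float:
    """Relative CNR: CNR of the compared image over CNR of the ground truth."""
    cnr_y = cnr(y, roi)
    if cnr_y == 0.0:
        raise ValueError("RCNR undefined: ground-truth CNR is zero")
    return cnr(x, roi) / cnr_y


def relative_difference_map(x, y) -> ImageGrid:
    """Signed (x - y) / max(y); the standard visual error map."""
    xa, ya = _check_pair(x, y)
    peak = float(ya.max())
    if peak <= 0:
        raise ValueError("relative difference map undefined: max(y) <= 0")
    spacing = y.spacing if isinstance(y, ImageGrid) else (1.0, 1.0)
    return ImageGrid((xa - ya) / peak, spacing=spacing, modality=Modality.PET)


def fraction_outside(diff_map, threshold: float = 0.10) -> float:
    """Fraction of pixels whose |relative difference| exceeds ``threshold``."""
    return float(np.mean(np.abs(_pix(diff_map)) > threshold))


@dataclass
class MetricsReport:
    """Per-image metric rows plus group mean/std summary."""

    rows: pd.DataFrame
    summary: pd.DataFrame

    METRICS = ["PSNR", "SSIM", "NMSE", "RCNR"]

    @classmethod
    def from_rows(cls, rows: pd.DataFrame) -> "MetricsReport":
        ok = rows[rows["error"].isna()] if "error" in rows else rows
        summary = (
            ok.groupby(["dose_label", "variant"])[cls.METRICS]
            .agg(["mean", "std"])
            .reset_index()
        )
        summary.columns = [
            "_".join(c).rstrip("_") if isinstance(c, tuple) else c for c in summary.columns
        ]
        return cls(rows=rows, summary=summary)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            self.rows.to_csv(fh, index=False)
            fh.write("# summary\n")
            self.summary.to_csv(fh, index=False)


def _metric_row(x, y, roi: ROISpec, cfg: MetricConfig) -> dict:
    return {
        "PSNR": psnr(x, y, cfg),
        "SSIM": ssim_global(x, y, cfg),
        "NMSE": nmse(x, y),
        "RCNR": rcnr(x, y, roi),
    }


def batch_report(
    manifest: pd.DataFrame,
    models: dict | None = None,
    cfg: MetricConfig = MetricConfig(),
) -> MetricsReport:
    """Evaluate every low-dose image (and optional restorations) vs truth.

    ``models`` maps variant names ('restored', 'restored+prior') to trained
    DWTN models; the 'input' variant (the raw low-dose image) is always
    reported. Rows that fail to load are recorded with an error message and
    the run continues.
    """
    from .io_formats import read_image
    from .training import restore_with_model

    models = models or {}
    records = []
    low = manifest[manifest["role"] == "lowdose"]
    for _, row in low.iterrows():
        try:
            truth = read_image(row["truth_path"])
            img = read_image(row["path"], dose_fraction=row["dose_fraction"])
            with np.load(row["roi_path"]) as d:
                roi_mask = d["pixels"].astype(bool)
            with np.load(row["background_path"]) as d:
                bg_mask = d["pixels"].astype(bool)
            roi = ROISpec(roi_mask, bg_mask)
            prior = read_image(row["prior_path"], modality=Modality.PRIOR)
        except Exception as exc:  # keep going per spec: per-row error entries
            records.append(
                {"subject": row["subject"], "dose_label": row["dose_label"], "variant": "input", "error": str(exc)}
            )
            continue
        base = {"subject": row["subject"], "dose_label": row["dose_label"], "error": np.nan}
        records.append({**base, "variant": "input", **_metric_row(img, truth, roi, cfg)})
        for variant, model in models.items():
            try:
                restored = restore_with_model(model, img, prior if model.cfg.use_prior else None, truth)
                records.append({**base, "variant": variant, **_metric_row(restored, truth, roi, cfg)})
            except Exception as exc:
                records.append({"subject": row["subject"], "dose_label": row["dose_label"], "variant": variant, "error": str(exc)})
    rows = pd.DataFrame(records)
    return MetricsReport.from_rows(rows)
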
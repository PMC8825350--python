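"""Image I/O, resizing and intensity normalization.

The pipeline's universal currency is :class:`ImageGrid`: a single 2D slice
with pixel spacing, a modality tag (PET or structural PRIOR), and — for
low-dose PET — the dose fraction it was simulated or acquired at. NIfTI is
the canonical on-disk format; DICOM is supported read-only; NPZ is a simple
array container used for fixtures and intermediate results.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "Modality",
    "ImageGrid",
    "ScaleRecord",
    "read_image",
    "write_image",
    "resize_bicubic",
    "normalize_intensity",
    "denormalize_intensity",
]


class Modality(str, enum.Enum):
    PET = "PET"
    PRIOR = "PRIOR"


class ImageFormatError(ValueError):
    """Raised when a file cannot be parsed in the requested format."""


class ImageValidationError(ValueError):
    """Raised when pixel data violates the ImageGrid invariants."""


@dataclass
class ImageGrid:
    """A 2D intensity image with physical spacing and dose metadata.

    pixels : 2D float array, finite everywhere.
    spacing : (row, col) pixel size in mm, strictly positive.
    modality : PET or PRIOR (the structural guidance image).
    dose_fraction : fraction of the full acquisition in (0, 1]; None for
        PRIOR images and for images where dose is not meaningful.
    """

    pixels: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)
    modality: Modality = Modality.PET
    dose_fraction: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ImageValidationError(
                f"ImageGrid requires a 2D array, got shape {self.pixels.shape}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ImageValidationError("ImageGrid pixels contain NaN or Inf")
        self.spacing = (float(self.spacing[0]), float(self.spacing[1]))
        if self.spacing[0] <= 0 or self.spacing[1] <= 0:
            raise ImageValidationError(f"spacing must be positive, got {self.spacing}")
        self.modality = Modality(self.modality)
        if self.dose_fraction is not None:
            df = float(self.dose_fraction)
            if not (0.0 < df <= 1.0):
                raise ImageValidationError(f"dose_fraction must lie in (0, 1], got {df}")
            self.dose_fraction = df

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class ScaleRecord:
    """Affine intensity record allowing exact inversion of normalization."""

    mode: str
    offset: float
    scale: float


def _check_written_pixels(arr: np.ndarray, path) -> np.ndarray:
    if not np.all(np.isfinite(arr)):
        raise ImageValidationError(f"file {path} contains non-finite pixel values")
    return np.asarray(arr, dtype=np.float64)


def read_image(
    path,
    format: str | None = None,
    slice_index: int | None = None,
    modality: Modality | str = Modality.PET,
    dose_fraction: float | None = None,
) -> ImageGrid:
    """Read a 2D slice from NIfTI, DICOM or NPZ.

    For 3D volumes ``slice_index`` selects an axial slice (last axis for
    NIfTI). Spacing is taken from the header when present, else 1.0 mm.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        name = path.name.lower()
        if name.endswith((".nii", ".nii.gz")):
            format = "nifti"
        elif name.endswith((".dcm", ".ima")):
            format = "dicom"
        elif name.endswith(".npz"):
            format = "npz"
        else:
            raise ImageFormatError(f"cannot infer format of {path}")

    if format == "nifti":
        import nibabel as nib

        try:
            img = nib.load(str(path))
        except Exception as exc:  # nibabel raises several types
            raise ImageFormatError(f"cannot parse {path} as NIfTI: {exc}") from exc
        arr = np.asanyarray(img.dataobj)
        zooms = img.header.get_zooms()
        if arr.ndim == 3:
            idx = arr.shape[2] // 2 if slice_index is None else slice_index
            arr = arr[:, :, idx]
        elif arr.ndim != 2:
            raise ImageFormatError(f"{path}: unsupported NIfTI dimensionality {arr.ndim}")
        spacing = (float(zooms[0]) or 1.0, float(zooms[1]) or 1.0) if len(zooms) >= 2 else (1.0, 1.0)
        pixels = _check_written_pixels(arr, path)
    elif format == "dicom":
        import pydicom

        try:
            ds = pydicom.dcmread(str(path))
            arr = ds.pixel_array.astype(np.float64)
        except Exception as exc:
            raise ImageFormatError(f"cannot parse {path} as DICOM: {exc}") from exc
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arr = arr * slope + intercept
        if arr.ndim == 3:
            idx = arr.shape[0] // 2 if slice_index is None else slice_index
            arr = arr[idx]
        ps = getattr(ds, "PixelSpacing", [1.0, 1.0])
        spacing = (float(ps[0]), float(ps[1]))
        pixels = _check_written_pixels(arr, path)
    elif format == "npz":
        try:
            with np.load(path, allow_pickle=False) as data:
                arr = data["pixels"]
                spacing = tuple(data["spacing"]) if "spacing" in data else (1.0, 1.0)
                if "modality" in data:
                    modality = str(data["modality"])
                if "dose_fraction" in data:
                    df = float(data["dose_fraction"])
                    dose_fraction = None if math.isnan(df) else df
        except ImageValidationError:
            raise
        except Exception as exc:
            raise ImageFormatError(f"cannot parse {path} as NPZ: {exc}") from exc
        if arr.ndim == 3:
            idx = arr.shape[0] // 2 if slice_index is None else slice_index
            arr = arr[idx]
        pixels = _check_written_pixels(arr, path)
    else:
        raise ImageFormatError(f"unknown format {format!r}")

    return ImageGrid(pixels=pixels, spacing=spacing, modality=modality, dose_fraction=dose_fraction)


def write_image(img: ImageGrid, path, format: str | None = None) -> Path:
    """Write an ImageGrid losslessly (float64 for npz, float32/64 for NIfTI)."""
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    if format is None:
        name = path.name.lower()
        format = "nifti" if name.endswith((".nii", ".nii.gz")) else "npz"

    if format == "nifti":
        import nibabel as nib

        affine = np.diag([img.spacing[0], img.spacing[1], 1.0, 1.0])
        nii = nib.Nifti1Image(img.pixels.astype(np.float64), affine)
        nii.header.set_zooms((img.spacing[0], img.spacing[1]))
        nib.save(nii, str(path))
    elif format == "npz":
        np.savez(
            path,
            pixels=img.pixels,
            spacing=np.asarray(img.spacing, dtype=np.float64),
            modality=np.str_(img.modality.value),
            dose_fraction=np.float64(
                math.nan if img.dose_fraction is None else img.dose_fraction
            ),
        )
    else:
        raise ImageFormatError(f"unknown format {format!r}")
    return path


# --- bicubic resampling -----------------------------------------------------
#
# Keys cubic-convolution kernel with a = -0.5 (the classical "bicubic" of
# image processing), applied separably with half-pixel sample centers and
# clamp-to-edge boundary handling. The kernel weights sum to 1 exactly for
# any sample phase, so constant images are reproduced to round-off.


def _keys_weights(t: np.ndarray) -> np.ndarray:
    """Keys (1981) cubic kernel, a=-0.5, evaluated at |t| <= 2."""
    at = np.abs(t)
    w = np.where(
        at <= 1.0,
        1.5 * at**3 - 2.5 * at**2 + 1.0,
        np.where(at < 2.0, -0.5 * at**3 + 2.5 * at**2 - 4.0 * at + 2.0, 0.0),
    )
    return w


def _resize_axis_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Dense (n_out, n_in) cubic interpolation matrix along one axis."""
    out_idx = np.arange(n_out)
    # half-pixel centers: output center maps to input coordinate
    src = (out_idx + 0.5) * (n_in / n_out) - 0.5
    base = np.floor(src).astype(int)
    frac = src - base
    mat = np.zeros((n_out, n_in))
    for k in range(-1, 3):
        idx = np.clip(base + k, 0, n_in - 1)
        w = _keys_weights(frac - k)
        np.add.at(mat, (out_idx, idx), w)
    # rows sum to 1 analytically; renormalize to kill accumulated round-off
    mat /= mat.sum(axis=1, keepdims=True)
    return mat


def resize_bicubic(img: ImageGrid, target_shape: tuple[int, int]) -> ImageGrid:
    """Resize to ``target_shape`` by separable bicubic interpolation.

    Physical spacing is rescaled so the field of view is preserved. When the
    target equals the current shape the image is returned bit-identically.
    """
    rows, cols = int(target_shape[0]), int(target_shape[1])
    if rows < 4 or cols < 4:
        raise ValueError(f"bicubic target must be at least 4x4, got {(rows, cols)}")
    r0, c0 = img.shape
    if (rows, cols) == (r0, c0):
        return replace(img, pixels=img.pixels.copy(), meta=dict(img.meta))
    m_rows = _resize_axis_matrix(r0, rows)
    m_cols = _resize_axis_matrix(c0, cols)
    out = m_rows @ img.pixels @ m_cols.T
    spacing = (img.spacing[0] * r0 / rows, img.spacing[1] * c0 / cols)
    return replace(img, pixels=out, spacing=spacing, meta=dict(img.meta))


def normalize_intensity(img: ImageGrid, mode: str = "minmax") -> tuple[ImageGrid, ScaleRecord]:
    """Map intensities to a unit range; returns the exact inverse record.

    minmax: (x - min) / (max - min) -> [0, 1]; a constant image maps to zeros
    with the offset recorded. max: x / max(x); errors on an all-zero image.
    """
    px = img.pixels
    if mode == "minmax":
        lo = float(px.min())
        hi = float(px.max())
        span = hi - lo
        if span == 0.0:
            rec = ScaleRecord("minmax", offset=lo, scale=1.0)
            return replace(img, pixels=np.zeros_like(px), meta=dict(img.meta)), rec
        rec = ScaleRecord("minmax", offset=lo, scale=span)
        return replace(img, pixels=(px - lo) / span, meta=dict(img.meta)), rec
    if mode == "max":
        hi = float(px.max())
        if hi == 0.0:
            raise ValueError("cannot max-normalize an all-zero image")
        rec = ScaleRecord("max", offset=0.0, scale=hi)
        return replace(img, pixels=px / hi, meta=dict(img.meta)), rec
    raise ValueError(f"unknown normalization mode {mode!r}")


def denormalize_intensity(img: ImageGrid, rec: ScaleRecord) -> ImageGrid:
    """Invert :func:`normalize_intensity` exactly (up to float round-off)."""
    return replace(img, pixels=img.pixels * rec.scale + rec.offset, meta=dict(img.meta))
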
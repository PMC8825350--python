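"""Synthetic paired low-/full-dose PET + structural-prior phantoms.

The clinical pelvic PET/MRI data this package targets is not publicly
available, so this module generates a statistical stand-in: pelvic-like 2D
phantoms built from ellipse primitives. Each subject has

* a full-dose PET activity map (the ground truth ``y``),
* a co-registered structural prior rendered on the *same* geometry but with
  different tissue contrast plus a smooth random intensity field — so the
  prior is informative about anatomy without duplicating PET contrast,
* one low-dose PET image per dose fraction, produced by an image-space
  count-thinning model: the truth is blurred by a Gaussian PSF, scaled to
  expected counts proportional to dose, Poisson-sampled, and scaled back.

The dose fractions default to {2.5, 5, 25, 50, 100}% , mirroring full-count
acquisitions thinned to shorter acquisition times. The Poisson model gives
the two properties the restoration method relies on: the low-dose image is
an unbiased estimate of the (blurred) truth, and its noise variance scales
as 1/fraction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .io_formats import ImageGrid, Modality, write_image

__all__ = [
    "Ellipse",
    "PhantomSpec",
    "DoseLevel",
    "DEFAULT_DOSE_LEVELS",
    "generate_phantom_pair",
    "phantom_masks",
    "simulate_dose",
    "sample_phantom_spec",
    "build_dataset",
]

#: default expected full-dose counts per activity unit per pixel; calibrated
#: so that low-dose input PSNR vs the truth spans roughly the mid-20s to
#: low-30s dB across fractions 2.5%..50% on the default phantoms.
DEFAULT_COUNTS_PER_UNIT = 60.0
DEFAULT_PSF_SIGMA = 1.5


@dataclass(frozen=True)
class Ellipse:
    center: tuple[float, float]  # (row, col) in pixels
    semi_axes: tuple[float, float]  # (a_row, a_col) in pixels
    rotation_deg: float
    pet_activity: float
    prior_intensity: float


@dataclass
class PhantomSpec:
    """Parametric pelvic-like phantom: background + ordered ellipse primitives."""

    shape: tuple[int, int]
    ellipses: list[Ellipse]
    background_activity: float = 0.0

    def __post_init__(self):
        if self.background_activity < 0:
            raise ValueError("background_activity must be non-negative")
        if not self.ellipses:
            raise ValueError("phantom needs at least one ellipse")
        for e in self.ellipses:
            if e.pet_activity < 0 or e.prior_intensity < 0:
                raise ValueError("activities and intensities must be non-negative")
        if not any(e.pet_activity > self.background_activity for e in self.ellipses):
            raise ValueError(
                "at least one ellipse must exceed background activity (no contrast)"
            )
        rows, cols = self.shape
        for e in self.ellipses:
            r = max(e.semi_axes)
            if (
                e.center[0] - r < 0
                or e.center[1] - r < 0
                or e.center[0] + r > rows - 1
                or e.center[1] + r > cols - 1
            ):
                raise ValueError(f"ellipse at {e.center} extends outside image bounds")


@dataclass(frozen=True)
class DoseLevel:
    """A dose fraction (ratio of reduced to full acquisition) with a label."""

    fraction: float
    label: str = ""

    def __post_init__(self):
        if not (0.0 < self.fraction <= 1.0):
            raise ValueError(f"dose fraction must lie in (0, 1], got {self.fraction}")
        if not self.label:
            object.__setattr__(self, "label", f"{self.fraction * 100:g}%")


DEFAULT_DOSE_LEVELS = [
    DoseLevel(0.025),
    DoseLevel(0.05),
    DoseLevel(0.25),
    DoseLevel(0.5),
    DoseLevel(1.0),
]


def _ellipse_mask(shape, e: Ellipse, scale: float = 1.0) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr = rr - e.center[0]
    dc = cc - e.center[1]
    th = np.deg2rad(e.rotation_deg)
    u = dr * np.cos(th) + dc * np.sin(th)
    v = -dr * np.sin(th) + dc * np.cos(th)
    a = max(e.semi_axes[0] * scale, 1e-9)
    b = max(e.semi_axes[1] * scale, 1e-9)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def generate_phantom_pair(spec: PhantomSpec, seed: int) -> tuple[ImageGrid, ImageGrid]:
    """Render the PET activity map and the structural prior for one subject.

    Ellipses are painted in order (later ones overwrite earlier ones). The
    prior shares the geometry but carries its own intensities plus a smooth
    seeded perturbation field, so PET and prior correlate without being
    copies of each other.
    """
    rng = np.random.default_rng(seed)
    pet = np.full(spec.shape, float(spec.background_activity))
    prior = np.zeros(spec.shape)
    for e in spec.ellipses:
        m = _ellipse_mask(spec.shape, e)
        pet[m] = e.pet_activity
        prior[m] = e.prior_intensity
    # smooth, low-amplitude field -> prior texture independent of PET
    bump = gaussian_filter(rng.standard_normal(spec.shape), sigma=min(spec.shape) / 12)
    amp = 0.08 * (prior.max() - prior.min() if prior.max() > prior.min() else 1.0)
    sd = float(bump.std())
    prior = np.clip(prior + amp * bump / (sd if sd > 0 else 1.0), 0.0, None)
    pet_img = ImageGrid(pet, modality=Modality.PET, dose_fraction=1.0)
    prior_img = ImageGrid(prior, modality=Modality.PRIOR)
    return pet_img, prior_img


def phantom_masks(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """(roi_mask, background_mask) for contrast measurements.

    ROI = the hottest ellipse (the 'lesion'); background = the interior of
    the body (first ellipse, shrunk) minus all other structures, dilated.
    """
    hot = max(spec.ellipses, key=lambda e: e.pet_activity)
    roi = _ellipse_mask(spec.shape, hot, scale=0.9)
    body = _ellipse_mask(spec.shape, spec.ellipses[0], scale=0.85)
    occupied = np.zeros(spec.shape, dtype=bool)
    for e in spec.ellipses[1:]:
        occupied |= _ellipse_mask(spec.shape, e, scale=1.6)
    occupied |= _ellipse_mask(spec.shape, hot, scale=1.6)
    bg = body & ~occupied
    if not roi.any() or not bg.any():
        raise ValueError("degenerate phantom: empty ROI or background mask")
    if (roi & bg).any():
        raise ValueError("ROI and background masks overlap")
    return roi, bg


def simulate_dose(
    pet_truth: ImageGrid,
    dose: DoseLevel,
    counts_per_unit: float = DEFAULT_COUNTS_PER_UNIT,
    psf_sigma_px: float = DEFAULT_PSF_SIGMA,
    seed: int = 0,
) -> ImageGrid:
    """Image-space dose-reduction model: PSF blur + Poisson count thinning.

    output = Poisson(blur(truth) * counts_per_unit * fraction)
             / (counts_per_unit * fraction)

    so E[output] = blur(truth) and Var[output] = blur(truth) / (c * fraction):
    halving the dose doubles the noise variance.
    """
    if counts_per_unit <= 0:
        raise ValueError("counts_per_unit must be positive")
    if psf_sigma_px < 0:
        raise ValueError("psf_sigma_px must be non-negative")
    px = pet_truth.pixels
    if (px < 0).any():
        raise ValueError("PET truth contains negative activity")
    lam_img = gaussian_filter(px, psf_sigma_px) if psf_sigma_px > 0 else px
    scale = counts_per_unit * dose.fraction
    rng = np.random.default_rng(seed)
    counts = rng.poisson(np.clip(lam_img, 0.0, None) * scale)
    out = counts.astype(np.float64) / scale
    return ImageGrid(
        out,
        spacing=pet_truth.spacing,
        modality=Modality.PET,
        dose_fraction=dose.fraction,
        meta={**pet_truth.meta, "dose_label": dose.label},
    )


def sample_phantom_spec(shape: tuple[int, int], rng: np.random.Generator) -> PhantomSpec:
    """Draw a randomized pelvic-like phantom: body, bladder, two bone
    structures and one hot lesion, with PET and prior contrasts decoupled."""
    rows, cols = shape
    cy, cx = rows / 2, cols / 2
    jit = lambda s: rng.uniform(-s, s)
    body = Ellipse(
        center=(cy + jit(rows * 0.02), cx + jit(cols * 0.02)),
        semi_axes=(rows * rng.uniform(0.36, 0.42), cols * rng.uniform(0.40, 0.46)),
        rotation_deg=jit(8),
        pet_activity=1.0,
        prior_intensity=rng.uniform(0.35, 0.45),
    )
    bones = [
        Ellipse(
            center=(cy + jit(rows * 0.03), cx + side * cols * rng.uniform(0.26, 0.32)),
            semi_axes=(rows * rng.uniform(0.10, 0.14), cols * rng.uniform(0.05, 0.07)),
            rotation_deg=side * rng.uniform(15, 30),
            pet_activity=0.4,
            prior_intensity=rng.uniform(0.85, 1.0),
        )
        for side in (-1, 1)
    ]
    bladder = Ellipse(
        center=(cy - rows * rng.uniform(0.08, 0.14), cx + jit(cols * 0.03)),
        semi_axes=(rows * rng.uniform(0.08, 0.12), cols * rng.uniform(0.08, 0.12)),
        rotation_deg=jit(20),
        pet_activity=rng.uniform(5.0, 8.0),
        prior_intensity=rng.uniform(0.15, 0.25),
    )
    lesion = Ellipse(
        center=(cy + rows * rng.uniform(0.10, 0.18), cx + jit(cols * 0.10)),
        semi_axes=(rows * rng.uniform(0.035, 0.06), cols * rng.uniform(0.035, 0.06)),
        rotation_deg=jit(45),
        pet_activity=rng.uniform(8.0, 12.0),
        prior_intensity=rng.uniform(0.5, 0.65),
    )
    return PhantomSpec(
        shape=shape,
        ellipses=[body, *bones, bladder, lesion],
        background_activity=0.05,
    )


def build_dataset(
    out_dir,
    n_subjects: int,
    dose_levels: list[DoseLevel] = None,
    shape: tuple[int, int] = (128, 128),
    counts_per_unit: float = DEFAULT_COUNTS_PER_UNIT,
    psf_sigma_px: float = DEFAULT_PSF_SIGMA,
    seed: int = 0,
) -> pd.DataFrame:
    """Write a paired dataset to disk and return its manifest.

    Per subject: one full-dose truth, one prior, and one low-dose image per
    fraction < 1. ROI/background masks derived from the phantom geometry are
    written alongside and referenced from every row of that subject.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects to allow a train/test split")
    dose_levels = list(DEFAULT_DOSE_LEVELS if dose_levels is None else dose_levels)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    root = np.random.default_rng(seed)
    subject_seeds = root.integers(0, 2**31 - 1, size=(n_subjects, 2))
    for s in range(n_subjects):
        sid = f"S{s:03d}"
        geom_rng = np.random.default_rng(int(subject_seeds[s, 0]))
        spec = sample_phantom_spec(shape, geom_rng)
        activity, prior = generate_phantom_pair(spec, seed=int(subject_seeds[s, 0]))
        # the stored full-dose truth is the ideal noise-free image at scanner
        # resolution: the activity map seen through the same PSF as the
        # low-dose images, so E[low dose] = truth exactly
        truth = ImageGrid(
            gaussian_filter(activity.pixels, psf_sigma_px) if psf_sigma_px > 0 else activity.pixels,
            spacing=activity.spacing,
            modality=Modality.PET,
            dose_fraction=1.0,
        )
        roi, bg = phantom_masks(spec)
        sub_dir = out_dir / sid
        sub_dir.mkdir(exist_ok=True)
        truth_path = sub_dir / "truth.nii"
        prior_path = sub_dir / "prior.nii"
        roi_path = sub_dir / "roi_mask.npz"
        bg_path = sub_dir / "background_mask.npz"
        write_image(truth, truth_path)
        write_image(prior, prior_path)
        np.savez(roi_path, pixels=roi.astype(np.uint8))
        np.savez(bg_path, pixels=bg.astype(np.uint8))
        common = dict(
            subject=sid,
            truth_path=str(truth_path),
            prior_path=str(prior_path),
            roi_path=str(roi_path),
            background_path=str(bg_path),
        )
        rows.append({**common, "role": "truth", "dose_label": "100%", "dose_fraction": 1.0, "path": str(truth_path)})
        rows.append({**common, "role": "prior", "dose_label": "", "dose_fraction": np.nan, "path": str(prior_path)})
        noise_rng = np.random.default_rng(int(subject_seeds[s, 1]))
        for dl in dose_levels:
            if dl.fraction >= 1.0:
                continue  # the 100% image *is* the truth
            low = simulate_dose(
                activity, dl, counts_per_unit, psf_sigma_px, seed=int(noise_rng.integers(0, 2**31 - 1))
            )
            low_path = sub_dir / f"lowdose_{dl.label.replace('%', 'pct').replace('.', 'p')}.nii"
            write_image(low, low_path)
            rows.append(
                {**common, "role": "lowdose", "dose_label": dl.label, "dose_fraction": dl.fraction, "path": str(low_path)}
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    with open(out_dir / "generation.json", "w") as fh:
        json.dump(
            {
                "n_subjects": n_subjects,
                "shape": list(shape),
                "dose_fractions": [dl.fraction for dl in dose_levels],
                "counts_per_unit": counts_per_unit,
                "psf_sigma_px": psf_sigma_px,
                "seed": seed,
            },
            fh,
            indent=2,
        )
    return manifest
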
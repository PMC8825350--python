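"""Training protocol: split, flip augmentation, LR schedule, Adam loop.

The recipe mirrors the standard restoration setup: Adam with default
moments, batch size 4, fixed epoch count, learning rate halved every 25
epochs, Gaussian weight initialization, and x4 flip augmentation of the
training set. The train/test split is 90/10 and is done at the *subject*
level by default so that no subject contributes images to both sides;
image-level splitting is available to mirror protocols that split pooled
slices directly.

Intensity handling: each low-dose input is max-normalized and its full-dose
target is divided by the same scale, so the network learns on a [0, ~1]
range and restorations are mapped back exactly. Priors are min-max
normalized independently.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .dwtn_model import DWTN, forward as model_forward, init_gaussian_, save_checkpoint
from .io_formats import ImageGrid, Modality, denormalize_intensity, normalize_intensity, read_image
from .losses import LossWeights, RandomConvExtractor, kernel_loss, mse_loss, perceptual_loss, total_loss

__all__ = [
    "TrainingConfig",
    "split_dataset",
    "augment_flips",
    "apply_flip",
    "lr_schedule",
    "init_weights_gaussian",
    "train",
    "restore_with_model",
]

FLIPS = ("none", "ud", "lr", "udlr")


@dataclass
class TrainingConfig:
    batch_size: int = 4
    epochs: int = 100
    lr0: float = 1e-3
    lr_step_epochs: int = 25
    lr_gamma: float = 0.5
    init_std: float | None = None
    seed: int = 0
    split_fraction: float = 0.9
    split_unit: str = "subject"

    def __post_init__(self):
        if not (0.0 < self.split_fraction < 1.0):
            raise ValueError("split_fraction must lie in (0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not (0.0 < self.lr_gamma <= 1.0):
            raise ValueError("lr_gamma must lie in (0, 1]")
        if self.split_unit not in ("subject", "image"):
            raise ValueError("split_unit must be 'subject' or 'image'")


def split_dataset(manifest: pd.DataFrame, cfg: TrainingConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive train/test split, deterministic for a seed.

    subject mode: whole subjects go to one side. image mode: low-dose sample
    rows are split individually (truth/prior reference rows accompany both
    sides so each manifest stays self-contained).
    """
    rng = np.random.default_rng(cfg.seed)
    has_role = "role" in manifest.columns
    if cfg.split_unit == "subject":
        units = sorted(manifest["subject"].unique())
        if len(units) < 2:
            raise ValueError("need at least 2 subjects to split")
        order = rng.permutation(len(units))
        n_train = int(round(len(units) * cfg.split_fraction))
        n_train = min(max(n_train, 1), len(units) - 1)
        train_ids = {units[i] for i in order[:n_train]}
        train = manifest[manifest["subject"].isin(train_ids)].reset_index(drop=True)
        test = manifest[~manifest["subject"].isin(train_ids)].reset_index(drop=True)
        return train, test
    # image-level
    samples = manifest[manifest["role"] == "lowdose"] if has_role else manifest
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to split")
    order = rng.permutation(len(samples))
    n_train = int(round(len(samples) * cfg.split_fraction))
    n_train = min(max(n_train, 1), len(samples) - 1)
    train_samples = samples.iloc[np.sort(order[:n_train])]
    test_samples = samples.iloc[np.sort(order[n_train:])]
    if has_role:
        refs = manifest[manifest["role"] != "lowdose"]
        train = pd.concat([refs, train_samples]).reset_index(drop=True)
        test = pd.concat([refs, test_samples]).reset_index(drop=True)
    else:
        train, test = train_samples.reset_index(drop=True), test_samples.reset_index(drop=True)
    return train, test


def apply_flip(arr: np.ndarray, flip: str) -> np.ndarray:
    """Apply a named flip; each tag is an involution."""
    if flip == "none":
        return arr
    if flip == "ud":
        return arr[::-1, :]
    if flip == "lr":
        return arr[:, ::-1]
    if flip == "udlr":
        return arr[::-1, ::-1]
    raise ValueError(f"unknown flip {flip!r}")


def augment_flips(manifest: pd.DataFrame) -> pd.DataFrame:
    """Quadruple the training samples with up-down/left-right flip variants.

    Every low-dose sample row is repeated once per flip tag; PET, prior and
    target are flipped jointly at load time. Reference (truth/prior) rows
    pass through untouched.
    """
    if len(manifest) == 0:
        raise ValueError("cannot augment an empty manifest")
    has_role = "role" in manifest.columns
    samples = manifest[manifest["role"] == "lowdose"] if has_role else manifest
    refs = manifest[manifest["role"] != "lowdose"] if has_role else manifest.iloc[0:0]
    out = []
    for flip in FLIPS:
        block = samples.copy()
        block["flip"] = flip
        out.append(block)
    aug = pd.concat(out).reset_index(drop=True)
    if len(refs):
        refs = refs.copy()
        refs["flip"] = "none"
        aug = pd.concat([refs, aug]).reset_index(drop=True)
    return aug


def lr_schedule(epoch: int, cfg: TrainingConfig) -> float:
    """Step decay: lr0 * gamma^floor(epoch / step)."""
    if epoch < 0:
        raise ValueError("epoch must be non-negative")
    return cfg.lr0 * cfg.lr_gamma ** (epoch // cfg.lr_step_epochs)


def init_weights_gaussian(model: DWTN, cfg: TrainingConfig) -> DWTN:
    """Zero-mean Gaussian re-initialization of all conv weights (seeded)."""
    return init_gaussian_(model, std=cfg.init_std, seed=cfg.seed)


def _load_sample(row, use_prior: bool) -> tuple[np.ndarray, np.ndarray]:
    """Returns (input channels stack, target) on the normalized scale."""
    low = read_image(row["path"], dose_fraction=row.get("dose_fraction"))
    truth = read_image(row["truth_path"])
    flip = row.get("flip", "none")
    low_px = apply_flip(low.pixels, flip)
    truth_px = apply_flip(truth.pixels, flip)
    scale = float(low_px.max())
    if scale <= 0:
        raise ValueError(f"degenerate low-dose image in {row['path']}")
    chans = [low_px / scale]
    if use_prior:
        prior = read_image(row["prior_path"], modality=Modality.PRIOR)
        prior_px = apply_flip(prior.pixels, flip)
        pr_norm, _ = normalize_intensity(ImageGrid(prior_px, modality=Modality.PRIOR), "minmax")
        chans.append(pr_norm.pixels)
    return np.stack(chans), truth_px / scale


def train(
    model: DWTN,
    train_manifest: pd.DataFrame,
    cfg: TrainingConfig,
    loss_weights: LossWeights = LossWeights(),
    extractor=None,
    kernel_subject: str = "generated_image",
    dose_label: str | None = None,
    checkpoint_dir=None,
    checkpoint_every: int = 0,
    start_epoch: int = 0,
) -> tuple[DWTN, pd.DataFrame]:
    """Run the Adam training loop; returns the model and per-epoch history.

    ``dose_label`` restricts training to one dose level (the default
    deployment trains one model per dose). A NaN loss aborts with a
    diagnostic naming the epoch.
    """
    samples = train_manifest[train_manifest["role"] == "lowdose"] if "role" in train_manifest.columns else train_manifest
    if dose_label is not None:
        samples = samples[samples["dose_label"] == dose_label]
    if len(samples) == 0:
        raise ValueError("no training samples after filtering")
    use_prior = model.cfg.use_prior
    loaded = [_load_sample(row, use_prior) for _, row in samples.iterrows()]
    xs = np.stack([x for x, _ in loaded])
    ys = np.stack([y for _, y in loaded])[:, None]

    if extractor is None:
        extractor = RandomConvExtractor(in_channels=1, channels=8, depth=2, seed=cfg.seed + 101)
    opt = nn.Adam(model.params(), lr=cfg.lr0)
    rng = np.random.default_rng(cfg.seed + 17)
    history = []
    n = len(xs)
    for epoch in range(start_epoch, start_epoch + cfg.epochs):
        opt.lr = lr_schedule(epoch, cfg)
        order = rng.permutation(n)
        ep = {"loss_total": 0.0, "loss_mse": 0.0, "loss_per": 0.0, "loss_ker": 0.0}
        n_batches = 0
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            xb = nn.Tensor(xs[idx])
            yb = nn.Tensor(ys[idx])
            y_hat = model(xb)
            l_mse = mse_loss(y_hat, yb)
            l_per = perceptual_loss(y_hat, yb, extractor)
            if kernel_subject == "generated_image":
                l_ker = kernel_loss("generated_image", y_hat=y_hat)
            else:
                l_ker = kernel_loss("model_weights", parameters=model.weight_params())
            loss = total_loss((l_mse, l_per, l_ker), loss_weights)
            if not np.isfinite(loss.data):
                raise RuntimeError(f"training diverged (non-finite loss) at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep["loss_total"] += loss.item()
            ep["loss_mse"] += l_mse.item()
            ep["loss_per"] += l_per.item()
            ep["loss_ker"] += l_ker.item() if isinstance(l_ker, nn.Tensor) else float(l_ker)
            n_batches += 1
        history.append(
            {"epoch": epoch, "lr": opt.lr, **{k: v / n_batches for k, v in ep.items()}}
        )
        if checkpoint_dir and checkpoint_every and (epoch + 1) % checkpoint_every == 0:
            save_checkpoint(
                model, Path(checkpoint_dir) / f"ckpt_epoch{epoch:04d}.npz", extra={"epoch": epoch}
            )
    return model, pd.DataFrame(history)


def restore_with_model(model: DWTN, low: ImageGrid, prior: ImageGrid | None = None, _truth=None) -> ImageGrid:
    """Normalize, run the network, and map back to the input's intensity scale."""
    low_norm, rec = normalize_intensity(low, "max")
    prior_norm = None
    if model.cfg.use_prior:
        if prior is None:
            raise ValueError("model requires a prior image")
        prior_norm, _ = normalize_intensity(prior, "minmax")
    out = model_forward(model, low_norm, prior_norm)
    return denormalize_intensity(out.restored, rec)
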
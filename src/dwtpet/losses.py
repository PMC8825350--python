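"""Composite training objective: weighted MSE + perceptual + kernel losses.

Loss_total = w_mse * Loss_MSE + w_vgg * Loss_per + w_kl * Loss_ker with
default weights (0.5, 0.5, 0.0001).

The perceptual term is a feature-space MSE through a *fixed* extractor. The
package ships two extractors: :class:`IdentityExtractor` (feature space =
pixel space, so the perceptual loss reduces exactly to the MSE) and
:class:`RandomConvExtractor`, a frozen, seeded stack of random 3x3
convolutions with leaky ReLU. A pretrained deep classifier backbone can be
plugged in through the same protocol when its weights are available; the
random stack provides the same contract (fixed, deterministic, non-trained
features) without any external weight file.

The kernel term is implemented in two modes: penalizing the energy of the
generated image (``subject="generated_image"``, the default) or the energy
of hidden-layer weights, i.e. classical weight decay
(``subject="model_weights"``).

Every loss accepts either plain ndarrays (returning a float) or autodiff
tensors (returning a scalar Tensor that participates in backprop).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import nn

__all__ = [
    "LossWeights",
    "IdentityExtractor",
    "RandomConvExtractor",
    "mse_loss",
    "perceptual_loss",
    "kernel_loss",
    "total_loss",
]


@dataclass(frozen=True)
class LossWeights:
    mse: float = 0.5
    vgg: float = 0.5
    kl: float = 0.0001

    def __post_init__(self):
        if self.mse < 0 or self.vgg < 0 or self.kl < 0:
            raise ValueError("loss weights must be non-negative")


def _maybe_float(result: nn.Tensor, was_array: bool):
    return result.item() if was_array else result


def _is_array(*xs) -> bool:
    return not any(isinstance(x, nn.Tensor) for x in xs)


class IdentityExtractor:
    """Feature extractor that returns its input unchanged."""

    identifier = "identity"

    def __call__(self, x):
        return x


class RandomConvExtractor:
    """Frozen stack of seeded random 3x3 convolutions + leaky ReLU.

    Weights are drawn once from a seeded generator and never updated, so the
    mapping is deterministic across runs and platforms. ``depth`` is the
    number of conv stages (the tap point of the feature space).
    """

    def __init__(self, in_channels: int = 1, channels: int = 8, depth: int = 3, slope: float = 0.2, seed: int = 1234):
        self.identifier = f"randconv-c{channels}-d{depth}-s{seed}"
        self.slope = slope
        rng = np.random.default_rng(seed)
        self.layers = []
        cin = in_channels
        for _ in range(depth):
            fan_in = cin * 9
            w = nn.Tensor(rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(channels, cin, 3, 3)))
            b = nn.Tensor(np.zeros(channels))
            self.layers.append((w, b))
            cin = channels

    def __call__(self, x):
        t = _as_nchw(x)
        for w, b in self.layers:
            t = nn.leaky_relu(nn.conv2d(t, w, b), self.slope)
        return t


def _as_nchw(x) -> nn.Tensor:
    """Lift a 2D array/tensor to NCHW for convolutional extractors."""
    t = nn.as_tensor(x)
    if t.data.ndim == 4:
        return t
    if t.data.ndim == 2:
        data = t.data[None, None]

        def backward(g):
            nn._accum(t, g[0, 0])

        return nn.Tensor(data, parents=(t,), backward=backward if (t.requires_grad or t._parents) else None)
    raise ValueError(f"expected 2D or 4D input, got ndim={t.data.ndim}")


def mse_loss(y_hat, y):
    """Pixelwise mean squared error between generated and ground-truth images."""
    was_array = _is_array(y_hat, y)
    a, b = nn.as_tensor(y_hat), nn.as_tensor(y)
    if a.data.shape != b.data.shape:
        raise ValueError(f"shape mismatch: {a.data.shape} vs {b.data.shape}")
    return _maybe_float(nn.mean_square_diff(a, b), was_array)


def perceptual_loss(y_hat, y, extractor):
    """Mean squared difference in the extractor's feature space."""
    was_array = _is_array(y_hat, y)
    if isinstance(extractor, IdentityExtractor):
        # feature space == pixel space; identical computation to mse_loss
        return mse_loss(y_hat, y)
    a, b = nn.as_tensor(y_hat), nn.as_tensor(y)
    if a.data.shape != b.data.shape:
        raise ValueError(f"shape mismatch: {a.data.shape} vs {b.data.shape}")
    if a.data.ndim not in (2, 4):
        raise ValueError("perceptual_loss expects 2D images or NCHW batches")
    fa = extractor(_as_nchw(a))
    fb = extractor(_as_nchw(b))
    return _maybe_float(nn.mean_square_diff(fa, fb), was_array)


def kernel_loss(subject: str = "generated_image", y_hat=None, parameters=None):
    """Eq-style kernel penalty.

    generated_image: mean of squared output pixels, E(y_hat^2).
    model_weights: mean of squared hidden-layer weights (weight decay).
    """
    if subject == "generated_image":
        if y_hat is None:
            raise ValueError("generated_image mode requires y_hat")
        was_array = _is_array(y_hat)
        return _maybe_float(nn.mean_square(nn.as_tensor(y_hat)), was_array)
    if subject == "model_weights":
        params = list(parameters or [])
        if not params:
            raise ValueError("model_weights mode requires a non-empty parameter set")
        was_array = _is_array(*params)
        tensors = [nn.as_tensor(p) for p in params]
        count = sum(t.data.size for t in tensors)
        acc = None
        for t in tensors:
            term = nn.scale(nn.mean_square(t), t.data.size / count)
            acc = term if acc is None else nn.add(acc, term)
        return _maybe_float(acc, was_array)
    raise ValueError(f"unknown kernel_loss subject {subject!r}")


def total_loss(components, weights: LossWeights = LossWeights()):
    """Weighted sum of (mse, perceptual, kernel) loss components."""
    m, p, k = components
    vals = [v.item() if isinstance(v, nn.Tensor) else float(v) for v in (m, p, k)]
    if any(math.isnan(v) or math.isinf(v) for v in vals):
        raise ValueError(f"non-finite loss component in {vals}")
    if _is_array(m, p, k):
        return weights.mse * float(m) + weights.vgg * float(p) + weights.kl * float(k)
    terms = [nn.scale(nn.as_tensor(m), weights.mse), nn.scale(nn.as_tensor(p), weights.vgg), nn.scale(nn.as_tensor(k), weights.kl)]
    return nn.add(nn.add(terms[0], terms[1]), terms[2])
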
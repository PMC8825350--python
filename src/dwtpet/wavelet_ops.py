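"""Orthonormal 2D Haar transform and pixel (un)shuffle.

These are the network's lossless down/upsampling operators. The Haar analysis
of each non-overlapping 2x2 block [A B; C D] uses the orthonormal scaling

    ll = (A+B+C+D)/2   lh = (A+B-C-D)/2
    hl = (A-B+C-D)/2   hh = (A-B-C+D)/2

so that the transform conserves energy exactly and its inverse is its
transpose. Subband ordering is (ll, lh, hl, hh): lh responds to horizontal
edges (variation down the rows), hl to vertical edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SubbandSet", "haar_dwt2", "haar_idwt2", "pixel_unshuffle", "pixel_shuffle"]

CONVENTION = "orthonormal-haar/ll-lh-hl-hh"


@dataclass(frozen=True)
class SubbandSet:
    """One level of 2D Haar coefficients: approximation + three details."""

    ll: np.ndarray
    lh: np.ndarray
    hl: np.ndarray
    hh: np.ndarray
    convention: str = CONVENTION

    def __post_init__(self):
        shapes = {self.ll.shape, self.lh.shape, self.hl.shape, self.hh.shape}
        if len(shapes) != 1:
            raise ValueError(f"subband shapes differ: {shapes}")

    def energy(self) -> float:
        return float(
            np.sum(self.ll**2) + np.sum(self.lh**2) + np.sum(self.hl**2) + np.sum(self.hh**2)
        )


def haar_dwt2(img: np.ndarray) -> SubbandSet:
    """One-level orthonormal Haar analysis of a 2D array with even dims."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"haar_dwt2 expects a 2D array, got shape {img.shape}")
    if img.shape[0] % 2 or img.shape[1] % 2:
        raise ValueError(f"haar_dwt2 requires even dimensions, got {img.shape}")
    a = img[0::2, 0::2]
    b = img[0::2, 1::2]
    c = img[1::2, 0::2]
    d = img[1::2, 1::2]
    return SubbandSet(
        ll=(a + b + c + d) / 2.0,
        lh=(a + b - c - d) / 2.0,
        hl=(a - b + c - d) / 2.0,
        hh=(a - b - c + d) / 2.0,
    )


def haar_idwt2(sub: SubbandSet) -> np.ndarray:
    """Perfect-reconstruction synthesis; inverse of :func:`haar_dwt2`."""
    ll, lh, hl, hh = sub.ll, sub.lh, sub.hl, sub.hh
    h2, w2 = ll.shape
    out = np.empty((2 * h2, 2 * w2), dtype=np.float64)
    out[0::2, 0::2] = (ll + lh + hl + hh) / 2.0
    out[0::2, 1::2] = (ll + lh - hl - hh) / 2.0
    out[1::2, 0::2] = (ll - lh + hl - hh) / 2.0
    out[1::2, 1::2] = (ll - lh - hl + hh) / 2.0
    return out


def pixel_unshuffle(img: np.ndarray, r: int) -> np.ndarray:
    """Space-to-depth: (H, W) -> (r*r, H/r, W/r); channel (i, j) holds the
    sub-lattice starting at row offset i, column offset j."""
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError("pixel_unshuffle expects a 2D array")
    r = int(r)
    if r < 1:
        raise ValueError("factor r must be >= 1")
    h, w = img.shape
    if h % r or w % r:
        raise ValueError(f"dims {img.shape} not divisible by r={r}")
    return (
        img.reshape(h // r, r, w // r, r).transpose(1, 3, 0, 2).reshape(r * r, h // r, w // r)
    )


def pixel_shuffle(stack: np.ndarray, r: int) -> np.ndarray:
    """Depth-to-space; exact inverse of :func:`pixel_unshuffle`."""
    stack = np.asarray(stack)
    r = int(r)
    if stack.ndim != 3 or stack.shape[0] != r * r:
        raise ValueError(f"expected (r*r, H, W) stack for r={r}, got {stack.shape}")
    _, h, w = stack.shape
    return stack.reshape(r, r, h, w).transpose(2, 0, 3, 1).reshape(h * r, w * r)
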
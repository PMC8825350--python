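"""Minimal reverse-mode autodiff engine on NumPy arrays.

The package trains a small convolutional network on CPU; everything it needs
— 2D convolution, leaky ReLU, tanh, channel concatenation, orthonormal Haar
down/upsampling of feature maps, and mean-square reductions — is implemented
here as differentiable ops on a :class:`Tensor` wrapper around ``numpy``
arrays, together with an Adam optimizer. Layout is NCHW throughout.

The engine is deliberately small: stride-1 "same" convolutions only, no
broadcasting beyond bias addition, float64 by default. That is all the DWTN
architecture requires, and it keeps every op exactly reproducible across runs.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "as_tensor",
    "add",
    "sub",
    "scale",
    "concat",
    "leaky_relu",
    "tanh",
    "conv2d",
    "dwt2_features",
    "idwt2_features",
    "mean_square",
    "mean_square_diff",
    "Adam",
]


class Tensor:
    """An ndarray node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):  # pragma: no cover - debug aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def backward(self):
        """Backpropagate from a scalar node through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def item(self) -> float:
        return float(self.data)

    # small operator sugar used by model code
    def __add__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return sub(self, other)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _accum(t: Tensor, g: np.ndarray) -> None:
    if t.requires_grad or t._parents:
        t.grad = g if t.grad is None else t.grad + g


def _needs_graph(*ts: Tensor) -> bool:
    return any(t.requires_grad or t._parents for t in ts)


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        _accum(a, g)
        _accum(b, g)

    return Tensor(out_data, parents=(a, b), backward=backward if _needs_graph(a, b) else None)


def sub(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data - b.data

    def backward(g):
        _accum(a, g)
        _accum(b, -g)

    return Tensor(out_data, parents=(a, b), backward=backward if _needs_graph(a, b) else None)


def scale(a, s: float) -> Tensor:
    a = as_tensor(a)
    s = float(s)
    out_data = a.data * s

    def backward(g):
        _accum(a, g * s)

    return Tensor(out_data, parents=(a,), backward=backward if _needs_graph(a) else None)


def concat(tensors, axis: int = 1) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _accum(t, g[tuple(sl)])

    return Tensor(out_data, parents=tuple(ts), backward=backward if _needs_graph(*ts) else None)


def leaky_relu(a, slope: float = 0.2) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0
    out_data = np.where(mask, a.data, slope * a.data)

    def backward(g):
        _accum(a, np.where(mask, g, slope * g))

    return Tensor(out_data, parents=(a,), backward=backward if _needs_graph(a) else None)


def tanh(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.tanh(a.data)

    def backward(g):
        _accum(a, g * (1.0 - out_data * out_data))

    return Tensor(out_data, parents=(a,), backward=backward if _needs_graph(a) else None)


def conv2d(x, w, b) -> Tensor:
    """Stride-1 'same' 2D convolution (cross-correlation), NCHW.

    x: (N, Cin, H, W); w: (Cout, Cin, k, k) with k odd; b: (Cout,).
    Implemented as im2col + BLAS matmul; the column matrix is kept for the
    weight gradient.
    """
    x, w, b = as_tensor(x), as_tensor(w), as_tensor(b)
    n, cin, h, wd = x.data.shape
    cout, cin_w, kh, kw = w.data.shape
    if cin != cin_w:
        raise ValueError(f"conv2d channel mismatch: input {cin}, weight {cin_w}")
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("conv2d requires odd kernel sizes")
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    # (N, Cin, H, W, kh, kw) view -> (N*H*W, Cin*kh*kw) columns
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * h * wd, cin * kh * kw
    )
    wmat = w.data.reshape(cout, cin * kh * kw)
    out = cols @ wmat.T + b.data
    out_data = out.reshape(n, h, wd, cout).transpose(0, 3, 1, 2)

    def backward(g):
        g_mat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * h * wd, cout)
        if w.requires_grad or w._parents:
            _accum(w, (g_mat.T @ cols).reshape(cout, cin, kh, kw))
        if b.requires_grad or b._parents:
            _accum(b, g_mat.sum(axis=0))
        if x.requires_grad or x._parents:
            dcols = (g_mat @ wmat).reshape(n, h, wd, cin, kh, kw)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i : i + h, j : j + wd] += dcols[:, :, :, :, i, j].transpose(
                        0, 3, 1, 2
                    )
            _accum(x, dxp[:, :, ph : ph + h, pw : pw + wd])

    return Tensor(
        out_data, parents=(x, w, b), backward=backward if _needs_graph(x, w, b) else None
    )


def _haar_split(x: np.ndarray):
    a = x[..., 0::2, 0::2]
    b = x[..., 0::2, 1::2]
    c = x[..., 1::2, 0::2]
    d = x[..., 1::2, 1::2]
    return a, b, c, d


def _haar_fwd(x: np.ndarray) -> np.ndarray:
    """(N,C,H,W) -> (N,4C,H/2,W/2); subband-major channel order ll|lh|hl|hh."""
    a, b, c, d = _haar_split(x)
    ll = (a + b + c + d) / 2.0
    lh = (a + b - c - d) / 2.0
    hl = (a - b + c - d) / 2.0
    hh = (a - b - c + d) / 2.0
    return np.concatenate([ll, lh, hl, hh], axis=1)


def _haar_inv(y: np.ndarray) -> np.ndarray:
    n, c4, h2, w2 = y.shape
    c = c4 // 4
    ll, lh, hl, hh = y[:, :c], y[:, c : 2 * c], y[:, 2 * c : 3 * c], y[:, 3 * c :]
    out = np.empty((n, c, 2 * h2, 2 * w2), dtype=y.dtype)
    out[:, :, 0::2, 0::2] = (ll + lh + hl + hh) / 2.0
    out[:, :, 0::2, 1::2] = (ll + lh - hl - hh) / 2.0
    out[:, :, 1::2, 0::2] = (ll - lh + hl - hh) / 2.0
    out[:, :, 1::2, 1::2] = (ll - lh - hl + hh) / 2.0
    return out


def dwt2_features(x) -> Tensor:
    """Orthonormal Haar analysis on every channel; subbands stacked as channels.

    The transform is orthonormal, so its adjoint (used in the backward pass)
    is the synthesis transform.
    """
    x = as_tensor(x)
    if x.data.shape[-1] % 2 or x.data.shape[-2] % 2:
        raise ValueError("dwt2_features requires even spatial dims")
    out_data = _haar_fwd(x.data)

    def backward(g):
        _accum(x, _haar_inv(g))

    return Tensor(out_data, parents=(x,), backward=backward if _needs_graph(x) else None)


def idwt2_features(y) -> Tensor:
    """Inverse of :func:`dwt2_features`; channel count must be divisible by 4."""
    y = as_tensor(y)
    if y.data.shape[1] % 4:
        raise ValueError("idwt2_features requires channels divisible by 4")
    out_data = _haar_inv(y.data)

    def backward(g):
        _accum(y, _haar_fwd(g))

    return Tensor(out_data, parents=(y,), backward=backward if _needs_graph(y) else None)


def mean_square(a) -> Tensor:
    """mean(a**2) as a scalar tensor."""
    a = as_tensor(a)
    out_data = np.mean(a.data**2)

    def backward(g):
        _accum(a, (2.0 / a.data.size) * a.data * g)

    return Tensor(out_data, parents=(a,), backward=backward if _needs_graph(a) else None)


def mean_square_diff(a, b) -> Tensor:
    """mean((a-b)**2); the pixelwise MSE reduction used by the losses."""
    a, b = as_tensor(a), as_tensor(b)
    if a.data.shape != b.data.shape:
        raise ValueError(f"shape mismatch: {a.data.shape} vs {b.data.shape}")
    diff = a.data - b.data
    out_data = np.mean(diff**2)

    def backward(g):
        gd = (2.0 / diff.size) * diff * g
        _accum(a, gd)
        _accum(b, -gd)

    return Tensor(out_data, parents=(a, b), backward=backward if _needs_graph(a, b) else None)


class Adam:
    """Adam with the standard default moments (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
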
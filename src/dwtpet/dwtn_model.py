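"""The DWTN restoration network.

A self-guided multi-scale CNN that maps a (normalized) low-dose PET slice —
optionally stacked with a co-registered structural prior as a second input
channel — to an estimate of the full-dose slice. Multi-resolution analysis
uses the orthonormal Haar transform as the down/upsampling operator: feature
maps are split channelwise into (ll, lh, hl, hh) subbands at half resolution
on the way down, and synthesized back on the way up, so no information is
discarded by resampling.

Level layout for ``levels`` = L (default 4), working top-down:

* the top (coarsest, 1/2^(L-1) resolution) level sees the (L-1)-fold Haar
  cascade of the stem features and applies two 3x3 convolutions, leaky ReLU,
  and a densely connected residual (DCR) block;
* each middle level fuses the inverse-transformed coarser features with its
  own subband stack (channel concat + 3x3 conv) and applies the same body;
* the full-resolution level, after the final fusion, applies a configurable
  number of DCR blocks, then splits into a main branch (conv + leaky ReLU)
  and an attention branch (two DCR blocks + tanh) whose outputs are summed,
  followed by residual refinement blocks and a closing 3x3 conv; the last
  layer is a single activation-free 1x1 convolution.

All convolutions are 3x3 stride 1 except that final 1x1. The network
predicts the restored image directly rather than a noise residual.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn
from .io_formats import ImageGrid, Modality

__all__ = [
    "NetworkConfig",
    "RestorationOutput",
    "DCRBlock",
    "ResidualBlock",
    "DWTN",
    "build_dwtn",
    "dcr_block",
    "forward",
    "init_gaussian_",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    ``base_channels`` defaults to 32 for full-scale use; 8 is the desk-scale
    setting used throughout the tests. ``attention_dcr`` is fixed at 2.
    ``init_std`` is the Gaussian weight-init std; None selects fan-in scaled
    std = sqrt(2 / fan_in) per layer (biases start at zero either way).
    """

    levels: int = 4
    base_channels: int = 32
    use_prior: bool = True
    leaky_slope: float = 0.2
    dcr_per_level: int = 1
    fullres_dcr_after_merge: int = 2
    attention_dcr: int = 2
    refine_residual_blocks: int = 3
    init_std: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.attention_dcr != 2:
            raise ValueError("attention_dcr is fixed at 2")
        if self.base_channels < 1 or self.dcr_per_level < 1:
            raise ValueError("channel/block counts must be positive")

    @property
    def in_channels(self) -> int:
        return 2 if self.use_prior else 1

    @property
    def div_factor(self) -> int:
        return 2 ** (self.levels - 1)


@dataclass
class RestorationOutput:
    """A restored full-dose estimate plus provenance of how it was made."""

    restored: ImageGrid
    provenance: dict = field(default_factory=dict)


class Conv:
    """3x3 (or 1x1) stride-1 'same' convolution layer with bias."""

    def __init__(self, cin: int, cout: int, kernel: int = 3):
        self.cin, self.cout, self.kernel = cin, cout, kernel
        self.w = nn.Tensor(np.zeros((cout, cin, kernel, kernel)), requires_grad=True)
        self.b = nn.Tensor(np.zeros(cout), requires_grad=True)

    def __call__(self, x):
        return nn.conv2d(x, self.w, self.b)

    def params(self):
        return [self.w, self.b]


class DCRBlock:
    """Densely connected residual block: three conv + leaky ReLU stages.

    Stage k convolves the concatenation of the block input and all previous
    stage outputs; the final stage restores the input channel count, so the
    block is shape-preserving.
    """

    def __init__(self, channels: int, slope: float = 0.2):
        self.channels = channels
        self.slope = slope
        self.convs = [
            Conv(channels, channels),
            Conv(2 * channels, channels),
            Conv(3 * channels, channels),
        ]

    def __call__(self, x):
        x = nn.as_tensor(x)
        if x.data.shape[1] != self.channels:
            raise ValueError(
                f"DCR block expects {self.channels} channels, got {x.data.shape[1]}"
            )
        s1 = nn.leaky_relu(self.convs[0](x), self.slope)
        s2 = nn.leaky_relu(self.convs[1](nn.concat([x, s1])), self.slope)
        s3 = nn.leaky_relu(self.convs[2](nn.concat([x, s1, s2])), self.slope)
        return s3

    def params(self):
        return [p for c in self.convs for p in c.params()]


class ResidualBlock:
    """conv -> leaky ReLU -> conv with an identity skip connection."""

    def __init__(self, channels: int, slope: float = 0.2):
        self.slope = slope
        self.conv1 = Conv(channels, channels)
        self.conv2 = Conv(channels, channels)

    def __call__(self, x):
        h = self.conv2(nn.leaky_relu(self.conv1(x), self.slope))
        return nn.add(x, h)

    def params(self):
        return self.conv1.params() + self.conv2.params()


class DWTN:
    """The assembled network; call with an (N, Cin, H, W) array or Tensor."""

    def __init__(self, cfg: NetworkConfig):
        self.cfg = cfg
        c = cfg.base_channels
        s = cfg.leaky_slope
        L = cfg.levels

        self.stem = Conv(cfg.in_channels, c)
        # top level input = (L-1)-fold DWT of stem features
        self.top_in = Conv(c * 4 ** (L - 1), c)
        self.top_conv = Conv(c, c)
        self.top_dcr = [DCRBlock(c, s) for _ in range(cfg.dcr_per_level)]
        # middle levels, coarse-to-fine: l = L-2 .. 1
        self.mid = []
        for lvl in range(L - 2, 0, -1):
            self.mid.append(
                {
                    "merge": Conv(c * 4**lvl + c, c),
                    "conv": Conv(c, c),
                    "dcr": [DCRBlock(c, s) for _ in range(cfg.dcr_per_level)],
                }
            )
        # one upsampling conv per level transition (coarse-to-fine)
        self.up = [Conv(c, 4 * c) for _ in range(L - 1)]
        # full-resolution level
        self.merge0 = Conv(2 * c, c)
        self.full_dcr = [DCRBlock(c, s) for _ in range(cfg.fullres_dcr_after_merge)]
        self.main_conv = Conv(c, c)
        self.att_dcr = [DCRBlock(c, s) for _ in range(cfg.attention_dcr)]
        self.refine = [ResidualBlock(c, s) for _ in range(cfg.refine_residual_blocks)]
        self.post_conv = Conv(c, c)
        self.final = Conv(c, 1, kernel=1)

        init_gaussian_(self, std=cfg.init_std, seed=cfg.seed)

    # -- introspection -------------------------------------------------
    def conv_layers(self) -> list[Conv]:
        convs = [self.stem, self.top_in, self.top_conv]
        convs += [c for b in self.top_dcr for c in b.convs]
        for lvl in self.mid:
            convs += [lvl["merge"], lvl["conv"]]
            convs += [c for b in lvl["dcr"] for c in b.convs]
        convs += list(self.up)
        convs += [self.merge0]
        convs += [c for b in self.full_dcr for c in b.convs]
        convs += [self.main_conv]
        convs += [c for b in self.att_dcr for c in b.convs]
        for r in self.refine:
            convs += [r.conv1, r.conv2]
        convs += [self.post_conv, self.final]
        return convs

    def params(self) -> list[nn.Tensor]:
        return [p for c in self.conv_layers() for p in c.params()]

    def weight_params(self) -> list[nn.Tensor]:
        """Hidden-layer convolution weights (no biases, no final layer)."""
        return [c.w for c in self.conv_layers()[:-1]]

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params()))

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self.cfg), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    # -- forward -------------------------------------------------------
    def __call__(self, x):
        x = nn.as_tensor(x)
        n, cin, h, w = x.data.shape
        if cin != self.cfg.in_channels:
            raise ValueError(
                f"expected {self.cfg.in_channels} input channels, got {cin}"
            )
        d = self.cfg.div_factor
        if h % d or w % d:
            raise ValueError(
                f"spatial dims {(h, w)} must be divisible by 2^(levels-1) = {d}"
            )
        s = self.cfg.leaky_slope

        s0 = nn.leaky_relu(self.stem(x), s)
        # analysis cascade of the stem features
        pyramid = [s0]
        for _ in range(self.cfg.levels - 1):
            pyramid.append(nn.dwt2_features(pyramid[-1]))

        # top level
        f = nn.leaky_relu(self.top_in(pyramid[-1]), s)
        f = nn.leaky_relu(self.top_conv(f), s)
        for blk in self.top_dcr:
            f = blk(f)

        # fuse downward through middle levels
        for i, lvl in enumerate(self.mid):
            up = nn.idwt2_features(self.up[i](f))
            f = nn.leaky_relu(lvl["merge"](nn.concat([pyramid[-2 - i], up])), s)
            f = nn.leaky_relu(lvl["conv"](f), s)
            for blk in lvl["dcr"]:
                f = blk(f)

        # full-resolution level
        up = nn.idwt2_features(self.up[-1](f))
        f = nn.leaky_relu(self.merge0(nn.concat([s0, up])), s)
        for blk in self.full_dcr:
            f = blk(f)
        main = nn.leaky_relu(self.main_conv(f), s)
        att = f
        for blk in self.att_dcr:
            att = blk(att)
        att = nn.tanh(att)
        f = nn.add(main, att)
        for blk in self.refine:
            f = blk(f)
        f = nn.leaky_relu(self.post_conv(f), s)
        return self.final(f)


def build_dwtn(cfg: NetworkConfig) -> DWTN:
    """Construct (and deterministically initialize) a DWTN from its config."""
    return DWTN(cfg)


def dcr_block(block: DCRBlock, features):
    """Apply a densely connected residual block to a feature tensor."""
    return block(features)


def init_gaussian_(model: DWTN, std: float | None = None, seed: int = 0) -> DWTN:
    """Initialize every conv weight with zero-mean Gaussian draws, biases zero.

    ``std=None`` uses fan-in scaling sqrt(2 / fan_in) per layer; a float fixes
    the same std everywhere. Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    for conv in model.conv_layers():
        fan_in = conv.cin * conv.kernel * conv.kernel
        s = float(std) if std is not None else float(np.sqrt(2.0 / fan_in))
        conv.w.data = rng.normal(0.0, s, size=conv.w.data.shape)
        conv.b.data = np.zeros_like(conv.b.data)
    return model


def forward(model: DWTN, low_dose: ImageGrid, prior: ImageGrid | None = None) -> RestorationOutput:
    """Restore a single slice; inputs are expected on the normalized scale."""
    cfg = model.cfg
    if cfg.use_prior:
        if prior is None:
            raise ValueError("model was built with use_prior=True but no prior was given")
        if prior.shape != low_dose.shape:
            raise ValueError(
                f"prior shape {prior.shape} does not match PET shape {low_dose.shape}"
            )
        x = np.stack([low_dose.pixels, prior.pixels])[None]
    else:
        x = low_dose.pixels[None, None]
    out = model(x).data[0, 0]
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("network produced non-finite output")
    restored = ImageGrid(
        pixels=out,
        spacing=low_dose.spacing,
        modality=Modality.PET,
        dose_fraction=None,
        meta={"restored_from_dose": low_dose.dose_fraction},
    )
    prov = {
        "config_hash": model.config_hash(),
        "input_ids": [low_dose.meta.get("id"), None if prior is None else prior.meta.get("id")],
    }
    return RestorationOutput(restored=restored, provenance=prov)


def save_checkpoint(model: DWTN, path, extra: dict | None = None) -> None:
    """Persist architecture config + parameters (npz with a JSON header)."""
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.params())}
    header = {"config": asdict(model.cfg), "extra": extra or {}}
    np.savez(path, __header__=np.str_(json.dumps(header)), **arrays)


def load_checkpoint(path) -> tuple[DWTN, dict]:
    with np.load(path, allow_pickle=False) as data:
        header = json.loads(str(data["__header__"]))
        model = DWTN(NetworkConfig(**header["config"]))
        params = model.params()
        for i, p in enumerate(params):
            arr = data[f"param_{i}"]
            if arr.shape != p.data.shape:
                raise ValueError("checkpoint does not match model architecture")
            p.data = arr.copy()
    return model, header["extra"]
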
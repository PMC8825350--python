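"""Schema-validated run configuration (YAML).

All knobs of a run — phantom generation, network architecture, training
protocol, loss weights and metric conventions — live in one YAML file that
is validated before anything touches the disk. Unknown keys are rejected so
that typos fail loudly.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .dwtn_model import NetworkConfig
from .losses import LossWeights
from .metrics import MetricConfig
from .synthetic_data import DEFAULT_COUNTS_PER_UNIT, DEFAULT_PSF_SIGMA, DoseLevel
from .training import TrainingConfig

__all__ = ["RunConfig", "ConfigError", "load_run_config"]


class ConfigError(ValueError):
    pass


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SyntheticSection(_Strict):
    n_subjects: int = 10
    shape: tuple[int, int] = (128, 128)
    dose_fractions: list[float] = [0.025, 0.05, 0.25, 0.5, 1.0]
    counts_per_unit: float = DEFAULT_COUNTS_PER_UNIT
    psf_sigma_px: float = DEFAULT_PSF_SIGMA

    def dose_levels(self) -> list[DoseLevel]:
        return [DoseLevel(f) for f in self.dose_fractions]


class NetworkSection(_Strict):
    levels: int = 4
    base_channels: int = 32
    use_prior: bool = True
    leaky_slope: float = 0.2
    dcr_per_level: int = 1
    fullres_dcr_after_merge: int = 2
    attention_dcr: int = 2
    refine_residual_blocks: int = 3
    init_std: float | None = None

    def to_config(self, seed: int) -> NetworkConfig:
        return NetworkConfig(seed=seed, **self.model_dump())


class TrainingSection(_Strict):
    batch_size: int = 4
    epochs: int = 100
    lr0: float = 1e-3
    lr_step_epochs: int = 25
    lr_gamma: float = 0.5
    init_std: float | None = None
    split_fraction: float = 0.9
    split_unit: str = "subject"
    dose_label: str | None = None

    def to_config(self, seed: int) -> TrainingConfig:
        d = self.model_dump()
        d.pop("dose_label")
        return TrainingConfig(seed=seed, **d)


class LossSection(_Strict):
    mse: float = 0.5
    vgg: float = 0.5
    kl: float = 0.0001
    extractor: str = "randconv"  # 'randconv' | 'identity'
    kernel_subject: str = "generated_image"

    def weights(self) -> LossWeights:
        return LossWeights(self.mse, self.vgg, self.kl)


class MetricsSection(_Strict):
    bit_depth: int | None = None
    c1: float = 0.01
    c2: float = 0.03

    def to_config(self) -> MetricConfig:
        return MetricConfig(bit_depth=self.bit_depth, c1=self.c1, c2=self.c2)


class RunConfig(_Strict):
    seed: int = 0
    synthetic: SyntheticSection = SyntheticSection()
    network: NetworkSection = NetworkSection()
    training: TrainingSection = TrainingSection()
    loss: LossSection = LossSection()
    metrics: MetricsSection = MetricsSection()


def load_run_config(path) -> RunConfig:
    """Parse + validate a YAML run config; None/empty file means defaults."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed YAML in {path}: {exc}") from exc
    except OSError as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    try:
        return RunConfig(**(raw or {}))
    except ValidationError as exc:
        raise ConfigError(f"invalid config {path}: {exc}") from exc
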
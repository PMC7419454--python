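"""GAN architecture and training configuration."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["GanConfig", "load_config"]


@dataclass
class GanConfig:
    """Architecture and training hyperparameters.

    ``gen_channels`` lists the generator's per-block output channels from
    the reshaped seed grid up to full resolution; each step after the first
    is preceded by a 2x nearest-neighbor upsample, so the seed grid is
    ``image_size / 2**(len(gen_channels) - 1)`` on a side.  The final entry
    must equal ``n_in``, the speckle bank's input channel count.
    ``disc_channels`` lists the discriminator's stride-2 block channels.
    """

    z_dim: int = 128
    image_size: int = 256
    n_in: int = 8
    n_sizes: int = 4
    gen_channels: tuple[int, ...] = (128, 64, 32, 16, 8, 8)
    disc_channels: tuple[int, ...] = (16, 32, 64, 128)
    attention_hidden: int = 8
    spade_hidden: int = 64
    softness: float = 0.5
    polar_speckle: bool = False
    use_speckle_layer: bool = True
    d_init_range: tuple[float, float] = (28.0, 48.0)
    lr_init: float = 3e-4
    lr_final: float = 1e-4
    lr_disc_scale: float = 1.0  # two-timescale trick: D lr = lr * scale
    disc_warmup_steps: int = 0  # D-only updates before alternating training
    lr_milestones: tuple[int, ...] = (200, 400)
    adam_beta1: float = 0.5
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    batch_size: int = 10
    epochs: int = 10
    fid_interval: int = 5
    fid_images: int = 0  # 0 -> one generated image per training pair
    seed: int = 0

    def __post_init__(self) -> None:
        self.gen_channels = tuple(self.gen_channels)
        self.disc_channels = tuple(self.disc_channels)
        self.lr_milestones = tuple(self.lr_milestones)
        self.d_init_range = tuple(self.d_init_range)
        if self.lr_init <= 0 or self.lr_final <= 0:
            raise ValueError("learning rates must be positive")
        if list(self.lr_milestones) != sorted(self.lr_milestones):
            raise ValueError("lr_milestones must be increasing")
        lo, hi = self.d_init_range
        if not (0 < lo <= hi <= self.image_size):
            raise ValueError("d_init_range must lie within (0, image_size]")
        if self.gen_channels[-1] != self.n_in:
            raise ValueError(
                f"last generator channel count {self.gen_channels[-1]} must "
                f"equal the speckle bank input count n_in={self.n_in}"
            )
        n_up = len(self.gen_channels) - 1
        if self.image_size % (2**n_up) != 0:
            raise ValueError("image_size must be divisible by 2**(#upsamples)")
        if self.image_size // (2**n_up) < 2:
            raise ValueError("too many generator blocks for this image size")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be positive")

    @property
    def seed_grid(self) -> int:
        return self.image_size // (2 ** (len(self.gen_channels) - 1))

    def to_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def from_dict(data: dict) -> "GanConfig":
        valid = {f.name for f in fields(GanConfig)}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return GanConfig(**data)


def load_config(path: str | Path) -> GanConfig:
    """Load a YAML key-value config file; unknown keys are rejected."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    return GanConfig.from_dict(data)
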
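"""Generator and discriminator assembly.

The generator maps a 128-dim Gaussian seed plus a segmentation mask to a
single-channel image in [0, 1]: linear reshape to the deepest grid, a stack
of residual blocks conditioned by SPADE with nearest-neighbor upsampling,
the multi-size speckle bank after the penultimate residual block (where
feature maps have reached full resolution), one final residual block and a
sigmoid-squashed output convolution.  The baseline variant replaces the
speckle bank with an identity mapping.

The discriminator concatenates the image with the one-hot mask and
downsamples with stride-2 residual blocks to a sigmoid probability.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat
from .config import GanConfig
from .layers import (
    BatchNorm2d,
    Conv2d,
    Linear,
    Module,
    N_MASK_CLASSES,
    SpeckleBank,
    Spade,
    one_hot_mask,
)

__all__ = ["Generator", "Discriminator", "build_generator", "build_discriminator"]


class SpadeResBlock(Module):
    """conv3x3 -> SPADE-norm -> ReLU -> conv3x3 -> SPADE-norm, additive skip
    (1x1 projection on channel change)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 spade_hidden: int = 64):
        self.conv1 = Conv2d(c_in, c_out, rng=rng)
        self.norm1 = Spade(c_out, rng=rng, hidden=spade_hidden)
        self.conv2 = Conv2d(c_out, c_out, rng=rng)
        self.norm2 = Spade(c_out, rng=rng, hidden=spade_hidden)
        self.skip = Conv2d(c_in, c_out, kernel=1, rng=rng) if c_in != c_out else None

    def forward(self, x: Tensor, mask_oh: np.ndarray) -> Tensor:
        h = self.norm1(self.conv1(x), mask_oh).relu()
        h = self.norm2(self.conv2(h), mask_oh)
        s = self.skip(x) if self.skip is not None else x
        return s + h

    __call__ = forward


class DiscResBlock(Module):
    """Stride-2 residual block: conv3x3/s2 -> BN -> ReLU -> conv3x3 -> BN,
    with a 1x1 stride-2 projection skip."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.conv1 = Conv2d(c_in, c_out, stride=2, rng=rng)
        self.norm1 = BatchNorm2d(c_out)
        self.conv2 = Conv2d(c_out, c_out, rng=rng)
        self.norm2 = BatchNorm2d(c_out)
        self.skip = Conv2d(c_in, c_out, kernel=1, stride=2, pad=0, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self.norm1(self.conv1(x)).relu()
        h = self.norm2(self.conv2(h))
        return self.skip(x) + h

    __call__ = forward


class Generator(Module):
    def __init__(self, cfg: GanConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        chans = cfg.gen_channels
        self.seed_grid = cfg.seed_grid
        self.fc = Linear(cfg.z_dim, chans[0] * self.seed_grid**2, rng=rng)
        self.head_block = SpadeResBlock(chans[0], chans[0], rng, cfg.spade_hidden)
        self.up_blocks = [
            SpadeResBlock(chans[i], chans[i + 1], rng, cfg.spade_hidden)
            for i in range(len(chans) - 1)
        ]
        if cfg.use_speckle_layer:
            d_init = rng.uniform(*cfg.d_init_range, size=cfg.n_sizes)
            self.bank = SpeckleBank(
                cfg.n_in, cfg.n_sizes, d_init, cfg.softness, rng,
                attention_hidden=cfg.attention_hidden, polar=cfg.polar_speckle,
            )
            tail_in = self.bank.n_out
        else:
            self.bank = None
            tail_in = cfg.n_in
        self.tail_block = SpadeResBlock(tail_in, cfg.n_in, rng, cfg.spade_hidden)
        self.out_conv = Conv2d(cfg.n_in, 1, rng=rng)

    def forward(
        self,
        z: np.ndarray,
        mask: np.ndarray,
        speckle_rng: np.random.Generator | int | None = None,
    ) -> Tensor:
        """(n, z_dim) seeds + (n, h, w) integer masks -> (n, 1, H, W) images.

        ``speckle_rng`` seeds the bank's fresh phase draw; pass an int or
        generator for reproducible speckle, or None for OS entropy.
        """
        z = np.atleast_2d(np.asarray(z, dtype=float))
        if z.shape[1] != self.cfg.z_dim:
            raise ValueError(f"z must have {self.cfg.z_dim} dims")
        mask_oh = one_hot_mask(mask)
        if mask_oh.shape[0] != z.shape[0]:
            raise ValueError("batch size mismatch between z and mask")
        if not isinstance(speckle_rng, np.random.Generator):
            speckle_rng = np.random.default_rng(speckle_rng)

        n = z.shape[0]
        x = self.fc(Tensor(z)).reshape(
            n, self.cfg.gen_channels[0], self.seed_grid, self.seed_grid
        )
        x = self.head_block(x, mask_oh)
        for block in self.up_blocks:
            x = x.upsample_nearest2x()
            x = block(x, mask_oh)
        if self.bank is not None:
            x = self.bank(x, speckle_rng)
        x = self.tail_block(x, mask_oh)
        return self.out_conv(x.relu()).sigmoid()

    __call__ = forward

    def window_sizes(self) -> np.ndarray:
        if self.bank is None:
            return np.array([])
        return self.bank.window_sizes()


class Discriminator(Module):
    def __init__(self, cfg: GanConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed + 1)
        chans = cfg.disc_channels
        self.stem = Conv2d(1 + N_MASK_CLASSES, chans[0], rng=rng)
        self.blocks = [
            DiscResBlock(chans[i], chans[i + 1], rng) for i in range(len(chans) - 1)
        ]
        self.fc = Linear(chans[-1], 1, rng=rng)

    def forward(self, image: Tensor | np.ndarray, mask: np.ndarray) -> Tensor:
        """(n, 1, h, w) images + (n, h, w) masks -> (n, 1) probabilities."""
        if not isinstance(image, Tensor):
            image = Tensor(np.asarray(image, dtype=float))
        mask_oh = one_hot_mask(mask)
        x = concat([image, Tensor(mask_oh)], axis=1)
        x = self.stem(x).relu()
        for block in self.blocks:
            x = block(x)
        pooled = x.relu().mean(axis=(2, 3))
        return self.fc(pooled).sigmoid()

    __call__ = forward


def build_generator(cfg: GanConfig) -> Generator:
    return Generator(cfg)


def build_discriminator(cfg: GanConfig) -> Discriminator:
    return Discriminator(cfg)
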
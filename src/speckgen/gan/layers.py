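"""Network layers: convolutions, batch normalization, SPADE and the
learnable speckle bank, all on the numpy autodiff engine."""

from __future__ import annotations

import numpy as np

from ..speckle import PolarGridSpec, _cart_to_polar_matrix, _polar_to_cart_matrix
from .autodiff import Tensor, concat, sparse_linear, speckle_transform
from .spectral import SpectralNormState, spectral_normalize_tensor

__all__ = [
    "Module",
    "Conv2d",
    "Linear",
    "BatchNorm2d",
    "Spade",
    "SpeckleBank",
    "one_hot_mask",
    "resize_mask_nearest",
]

N_MASK_CLASSES = 3


class Module:
    """Tiny module base: recursive parameter discovery in attribute order."""

    training: bool = True

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out: list[tuple[str, Tensor]] = []
        for key, val in vars(self).items():
            name = f"{prefix}{key}"
            if isinstance(val, Tensor) and val.requires_grad:
                out.append((name, val))
            elif isinstance(val, Module):
                out.extend(val.named_parameters(f"{name}."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(f"{name}.{i}."))
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append((f"{name}.{i}", item))
        return out

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def train(self, flag: bool = True) -> None:
        self.training = flag
        for val in vars(self).values():
            if isinstance(val, Module):
                val.train(flag)
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        item.train(flag)

    def eval(self) -> None:
        self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise ValueError(f"state dict mismatch on keys: {sorted(missing)}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.asarray(state[name], dtype=float).copy()


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int = 3, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None,
                 spectral_norm: bool = True, bias: bool = True):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (c_in * kernel * kernel))
        self.weight = Tensor.param(
            rng.normal(0.0, scale, (c_out, c_in, kernel, kernel)))
        self.bias = Tensor.param(np.zeros(c_out)) if bias else None
        self.stride = stride
        self.pad = kernel // 2 if pad is None else pad
        self.sn_state = (
            SpectralNormState.for_weight(self.weight.data, seed=int(rng.integers(1 << 31)))
            if spectral_norm else None
        )

    def forward(self, x: Tensor) -> Tensor:
        w = self.weight
        if self.sn_state is not None:
            w = spectral_normalize_tensor(w, self.sn_state, update=self.training)
        return x.conv2d(w, self.bias, stride=self.stride, pad=self.pad)

    __call__ = forward


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None,
                 spectral_norm: bool = True):
        rng = rng or np.random.default_rng(0)
        self.weight = Tensor.param(rng.normal(0.0, 1.0 / np.sqrt(n_in), (n_in, n_out)))
        self.bias = Tensor.param(np.zeros(n_out))
        # sigma_max is orientation-invariant, so normalize (in, out) directly
        self.sn_state = (
            SpectralNormState.for_weight(self.weight.data, seed=int(rng.integers(1 << 31)))
            if spectral_norm else None
        )

    def forward(self, x: Tensor) -> Tensor:
        w = self.weight
        if self.sn_state is not None:
            w = spectral_normalize_tensor(w, self.sn_state, update=self.training)
        return x @ w + self.bias

    __call__ = forward


class BatchNorm2d(Module):
    """Channel-wise batch normalization with optional learned affine.

    Training mode uses batch statistics over (sample, height, width) and
    updates running averages; eval mode uses the running averages.
    """

    def __init__(self, channels: int, affine: bool = True, eps: float = 1e-5,
                 momentum: float = 0.1):
        self.gamma = Tensor.param(np.ones(channels)) if affine else None
        self.beta = Tensor.param(np.zeros(channels)) if affine else None
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def standardize(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean
                + self.momentum * mu.data.ravel()
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var
                + self.momentum * var.data.ravel()
            )
            return (x - mu) / ((var + self.eps) ** 0.5)
        mu = Tensor(self.running_mean[None, :, None, None])
        var = Tensor(self.running_var[None, :, None, None])
        return (x - mu) / ((var + self.eps) ** 0.5)

    def forward(self, x: Tensor) -> Tensor:
        out = self.standardize(x)
        if self.gamma is not None:
            out = out * self.gamma.reshape(1, -1, 1, 1) + self.beta.reshape(1, -1, 1, 1)
        return out

    __call__ = forward


def one_hot_mask(mask: np.ndarray, n_classes: int = N_MASK_CLASSES) -> np.ndarray:
    """(n, h, w) integer labels -> (n, n_classes, h, w) float one-hot."""
    mask = np.asarray(mask)
    if mask.ndim == 2:
        mask = mask[None]
    out = np.zeros((mask.shape[0], n_classes, *mask.shape[1:]))
    for c in range(n_classes):
        out[:, c] = mask == c
    return out


def resize_mask_nearest(mask_oh: np.ndarray, h: int, w: int) -> np.ndarray:
    """Nearest-neighbor resize of a one-hot mask batch to (h, w)."""
    src_h, src_w = mask_oh.shape[-2], mask_oh.shape[-1]
    ri = np.minimum((np.arange(h) * src_h) // h, src_h - 1)
    ci = np.minimum((np.arange(w) * src_w) // w, src_w - 1)
    return mask_oh[..., ri[:, None], ci[None, :]]


class Spade(Module):
    """Spatially-adaptive normalization.

    The (one-hot) mask is resized to the feature resolution, passed through a
    shared 3x3 convolution with 64 output channels and a ReLU, and mapped by
    two more convolutions to per-pixel gamma and beta.  The input features
    are standardized per channel over batch and space first.
    """

    def __init__(self, channels: int, rng: np.random.Generator,
                 mask_channels: int = N_MASK_CLASSES, hidden: int = 64,
                 spectral_norm: bool = True):
        self.bn = BatchNorm2d(channels, affine=False)
        self.shared = Conv2d(mask_channels, hidden, rng=rng, spectral_norm=spectral_norm)
        self.gamma_conv = Conv2d(hidden, channels, rng=rng, spectral_norm=spectral_norm)
        self.beta_conv = Conv2d(hidden, channels, rng=rng, spectral_norm=spectral_norm)
        # bias gamma toward 1 so an untrained layer is near-neutral
        self.gamma_conv.bias.data[:] = 1.0

    def forward(self, x: Tensor, mask_oh: np.ndarray) -> Tensor:
        h, w = x.data.shape[-2], x.data.shape[-1]
        m = Tensor(resize_mask_nearest(mask_oh, h, w))
        hid = self.shared(m).relu()
        gamma = self.gamma_conv(hid)
        beta = self.beta_conv(hid)
        return gamma * self.bn.standardize(x) + beta

    __call__ = forward


class SpeckleBank(Module):
    """Learnable multi-size speckle layer for (n, n_in, h, w) features.

    Each input channel is speckled at ``n_sizes`` learnable window edge
    lengths (fresh uniform phases per forward pass), producing
    ``n_in * n_sizes`` output maps weighted by squeeze-excitation channel
    attention (global sum pool, two linear layers, sigmoid).  Output channel
    blocks are size-major: block s holds all input channels at size s.

    With ``polar`` set, features are warped Cartesian -> polar, speckled in
    the rectangular domain and warped back, so grains curve around the
    image centre.
    """

    def __init__(self, n_in: int, n_sizes: int, d_init: np.ndarray,
                 softness: float, rng: np.random.Generator,
                 attention_hidden: int = 8, polar: bool = False,
                 spectral_norm: bool = True):
        if len(d_init) != n_sizes:
            raise ValueError("d_init must have one entry per window size")
        self.n_in = n_in
        self.n_sizes = n_sizes
        self.softness = softness
        self.polar = polar
        self.d = [Tensor.param(np.array(float(v)), name=f"d{i}")
                  for i, v in enumerate(d_init)]
        self.att1 = Linear(n_in, attention_hidden, rng=rng, spectral_norm=spectral_norm)
        self.att2 = Linear(attention_hidden, n_in * n_sizes, rng=rng,
                           spectral_norm=spectral_norm)

    @property
    def n_out(self) -> int:
        return self.n_in * self.n_sizes

    def window_sizes(self) -> np.ndarray:
        return np.array([float(t.data) for t in self.d])

    def forward(self, x: Tensor, rng: np.random.Generator) -> Tensor:
        n, c, h, w = x.data.shape
        if c != self.n_in:
            raise ValueError(f"expected {self.n_in} channels, got {c}")
        coeff = self.att2(self.att1(x.sum(axis=(2, 3))).relu()).sigmoid()

        domain = x
        if self.polar:
            spec = PolarGridSpec.default(h, w)
            m_fwd = _cart_to_polar_matrix(spec, h, w)
            m_bwd = _polar_to_cart_matrix(spec, h, w)
            domain = sparse_linear(x, m_fwd, (spec.n_radii, spec.n_angles))
        dh, dw = domain.data.shape[-2], domain.data.shape[-1]

        blocks = []
        for s in range(self.n_sizes):
            phases = rng.uniform(0.0, 2.0 * np.pi, (n, c, dh, dw))
            d_eff = self.d[s].clip(2.0, float(min(dh, dw)))
            speckled = speckle_transform(domain, d_eff, phases, self.softness)
            if self.polar:
                speckled = sparse_linear(speckled, m_bwd, (h, w))
            blocks.append(speckled)
        out = concat(blocks, axis=1)
        return out * coeff.reshape(n, self.n_out, 1, 1)

    __call__ = forward
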
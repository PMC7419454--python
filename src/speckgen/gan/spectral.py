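"""Spectral weight normalization via power iteration."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor

__all__ = ["SpectralNormState", "spectral_normalize", "spectral_normalize_tensor"]


@dataclass
class SpectralNormState:
    """Persistent left singular-vector estimate for one weight."""

    u: np.ndarray
    n_power_iterations: int = 1

    @staticmethod
    def for_weight(weight: np.ndarray, seed: int = 0,
                   n_power_iterations: int = 1) -> "SpectralNormState":
        out_dim = weight.shape[0]
        u = np.random.default_rng(seed).normal(size=out_dim)
        return SpectralNormState(u=u / np.linalg.norm(u),
                                 n_power_iterations=n_power_iterations)


def _power_iterate(w2d: np.ndarray, state: SpectralNormState) -> tuple[np.ndarray, np.ndarray]:
    u = state.u
    v = None
    for _ in range(state.n_power_iterations):
        v = w2d.T @ u
        v = v / max(np.linalg.norm(v), 1e-12)
        u = w2d @ v
        u = u / max(np.linalg.norm(u), 1e-12)
    state.u = u
    return u, v


def spectral_normalize(weight: np.ndarray, state: SpectralNormState) -> np.ndarray:
    """Divide a weight by its estimated top singular value.

    The weight is viewed as a 2-D matrix (out-features x rest); ``state.u``
    is advanced by ``n_power_iterations`` power-iteration steps.
    """
    weight = np.asarray(weight, dtype=float)
    w2d = weight.reshape(weight.shape[0], -1)
    u, v = _power_iterate(w2d, state)
    sigma = float(u @ w2d @ v)
    return weight / sigma


def spectral_normalize_tensor(
    weight: Tensor, state: SpectralNormState, update: bool = True
) -> Tensor:
    """Autodiff version: sigma is recomputed as ``u^T W v`` with u, v held
    constant, so gradients flow through both the division and sigma (the
    standard treatment of the cited method).  With ``update=False`` (eval
    mode) the stored ``u`` is used without advancing the power iteration,
    keeping repeated forwards bit-identical."""
    w2d = weight.data.reshape(weight.data.shape[0], -1)
    if update:
        u, v = _power_iterate(w2d, state)
    else:
        u = state.u
        v = w2d.T @ u
        v = v / max(np.linalg.norm(v), 1e-12)
    uv = np.outer(u, v).reshape(weight.data.shape)
    sigma = (weight * Tensor(uv)).sum()
    return weight * (1.0 / sigma)
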
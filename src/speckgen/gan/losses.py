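"""Non-saturating GAN losses.

``L_D = -mean log D(real) - mean log(1 - D(fake))`` and
``L_G = -mean log D(fake)``; probabilities are clamped to
``[1e-7, 1 - 1e-7]`` before the logarithm.  Both functions accept either
plain numpy arrays (returning a float) or autodiff tensors (returning a
scalar tensor for backpropagation).
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["loss_discriminator", "loss_generator", "PROB_CLAMP"]

PROB_CLAMP = 1e-7


def _as_tensor(p) -> tuple[Tensor, bool]:
    if isinstance(p, Tensor):
        return p, True
    return Tensor(np.asarray(p, dtype=float)), False


def loss_discriminator(d_real, d_fake):
    """Discriminator loss; 0 for a perfect discriminator."""
    r, r_live = _as_tensor(d_real)
    f, f_live = _as_tensor(d_fake)
    r = r.clip(PROB_CLAMP, 1.0 - PROB_CLAMP)
    f = f.clip(PROB_CLAMP, 1.0 - PROB_CLAMP)
    loss = -(r.log().mean()) - ((1.0 - f).log().mean())
    if r_live or f_live:
        return loss
    return float(loss.data)


def loss_generator(d_fake):
    """Generator loss; ln 2 when the discriminator outputs 0.5 everywhere."""
    f, live = _as_tensor(d_fake)
    f = f.clip(PROB_CLAMP, 1.0 - PROB_CLAMP)
    loss = -(f.log().mean())
    return loss if live else float(loss.data)
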
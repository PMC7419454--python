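"""Image-set and segmentation evaluation metrics.

Fréchet distance between Gaussian feature fits (FID), per-class gray-value
Jensen-Shannon divergence, SSIM, Dice coefficient and the Dubuisson-Jain
modified Hausdorff distance.

FID is embedder-agnostic: any deterministic image -> feature-vector map can
be plugged in.  The default "desk" embedder is a fixed-seed random strided
convolutional projection to 64 features — it needs no downloads and makes
FID values comparable only within a fixed embedder, which is all the
library's own comparisons require.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import signal

__all__ = [
    "GaussianStats",
    "ClassHistogram",
    "DeskEmbedder",
    "embed_images",
    "gaussian_stats",
    "fid",
    "relative_improvement",
    "class_gray_histogram",
    "js_divergence",
    "ssim",
    "dice",
    "contour_points",
    "modified_hausdorff",
]


# ---------------------------------------------------------------------------
# FID
# ---------------------------------------------------------------------------

@dataclass
class GaussianStats:
    """Mean vector and covariance matrix of embedded image features."""

    mu: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        if self.cov.shape != (self.mu.size, self.mu.size):
            raise ValueError("covariance shape inconsistent with mean")
        if not np.allclose(self.cov, self.cov.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")


class DeskEmbedder:
    """Deterministic 3-layer strided random convolutional projection.

    Layers: three 3x3 stride-2 convolutions (channels 1 -> 16 -> 32 -> 64)
    with fixed Gaussian weights drawn from a frozen seed, ReLU between
    layers, then global average pooling to a 64-dim feature vector.  Works
    for any input size >= 8x8.
    """

    name = "desk"
    feature_dim = 64

    def __init__(self, seed: int = 1234) -> None:
        rng = np.random.default_rng(seed)
        chans = [1, 16, 32, 64]
        self._kernels = [
            rng.normal(0.0, 1.0 / np.sqrt(9 * cin), (cout, cin, 3, 3))
            for cin, cout in zip(chans[:-1], chans[1:])
        ]

    def __call__(self, image: np.ndarray) -> np.ndarray:
        from ._conv import conv2d_forward

        x = np.asarray(image, dtype=float)[None, None, :, :]  # (1, 1, h, w)
        for li, kern in enumerate(self._kernels):
            x = conv2d_forward(x, kern, stride=2, pad=1)
            if li < len(self._kernels) - 1:
                x = np.maximum(x, 0.0)
        return x[0].mean(axis=(1, 2))


def embed_images(
    images: Sequence[np.ndarray], embedder: Callable[[np.ndarray], np.ndarray]
) -> np.ndarray:
    """Stack per-image feature vectors into an (n, feature_dim) matrix."""
    if len(images) == 0:
        raise ValueError("empty image list")
    return np.stack([np.asarray(embedder(img), dtype=float) for img in images])


def gaussian_stats(features: np.ndarray) -> GaussianStats:
    """Sample mean and unbiased (n-1) covariance of feature rows."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[0] < 2:
        raise ValueError("need a 2-D feature matrix with >= 2 rows")
    mu = features.mean(axis=0)
    cov = np.cov(features, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    return GaussianStats(mu=mu, cov=cov)


def _trace_sqrt_product(c1: np.ndarray, c2: np.ndarray) -> float:
    """Tr((C1 C2)^{1/2}) via eigendecomposition of C1^{1/2} C2 C1^{1/2}."""
    vals1, vecs1 = np.linalg.eigh(c1)
    vals1 = np.clip(vals1, 0.0, None)
    c1h = (vecs1 * np.sqrt(vals1)) @ vecs1.T
    inner = c1h @ c2 @ c1h
    inner = (inner + inner.T) / 2.0
    try:
        vals = np.linalg.eigvalsh(inner)
    except np.linalg.LinAlgError:
        jitter = 1e-6 * np.eye(inner.shape[0])
        vals = np.linalg.eigvalsh(inner + jitter)
    return float(np.sum(np.sqrt(np.clip(vals, 0.0, None))))


def fid(a: GaussianStats, b: GaussianStats) -> float:
    """Fréchet distance between two Gaussian feature fits.

    ``||mu1 - mu2||^2 + Tr(C1 + C2 - 2 (C1 C2)^{1/2})``, with the matrix
    square root taken through the symmetrized product and tiny negative
    remainders clipped to zero.
    """
    if a.mu.shape != b.mu.shape:
        raise ValueError("feature dimension mismatch")
    diff = float(np.sum((a.mu - b.mu) ** 2))
    trace_term = float(np.trace(a.cov) + np.trace(b.cov)) - 2.0 * _trace_sqrt_product(
        a.cov, b.cov
    )
    return diff + max(trace_term, 0.0) if trace_term < 0 else diff + trace_term


def relative_improvement(worse: float, better: float) -> float:
    """Percentage improvement of a smaller score over a larger one,
    relative to the smaller: ``100 * (worse - better) / better``."""
    if better <= 0:
        raise ValueError("scores must be positive")
    return 100.0 * (worse - better) / better


# ---------------------------------------------------------------------------
# gray-value histograms and Jensen-Shannon divergence
# ---------------------------------------------------------------------------

@dataclass
class ClassHistogram:
    """Normalized gray-value histogram of one segmentation class."""

    bin_edges: np.ndarray
    probabilities: np.ndarray
    class_label: int

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if np.any(self.probabilities < 0):
            raise ValueError("negative probability")
        if abs(self.probabilities.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")


def class_gray_histogram(
    image: np.ndarray, mask: np.ndarray, class_label: int, n_bins: int = 256
) -> ClassHistogram:
    """Histogram of image intensities over pixels of one mask class."""
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ValueError("image/mask shape mismatch")
    sel = image[mask == class_label]
    if sel.size == 0:
        raise ValueError(f"class {class_label} absent from mask")
    counts, edges = np.histogram(sel, bins=n_bins, range=(0.0, 1.0))
    return ClassHistogram(
        bin_edges=edges,
        probabilities=counts / counts.sum(),
        class_label=class_label,
    )


def js_divergence(p: ClassHistogram, q: ClassHistogram, eps: float = 1e-12) -> float:
    """Jensen-Shannon divergence (natural log) between two histograms with
    identical binning; smoothed by ``eps`` so empty bins are harmless.
    Lies in [0, ln 2]."""
    if p.probabilities.shape != q.probabilities.shape or not np.allclose(
        p.bin_edges, q.bin_edges
    ):
        raise ValueError("histograms must share binning")
    pp = p.probabilities + eps
    qq = q.probabilities + eps
    pp = pp / pp.sum()
    qq = qq / qq.sum()
    m = 0.5 * (pp + qq)
    kl_pm = float(np.sum(pp * np.log(pp / m)))
    kl_qm = float(np.sum(qq * np.log(qq / m)))
    return 0.5 * kl_pm + 0.5 * kl_qm


# ---------------------------------------------------------------------------
# SSIM
# ---------------------------------------------------------------------------

def _gaussian_kernel_1d(size: int, sigma: float) -> np.ndarray:
    x = np.arange(size) - (size - 1) / 2.0
    k = np.exp(-(x**2) / (2.0 * sigma**2))
    return k / k.sum()


def ssim(
    a: np.ndarray,
    b: np.ndarray,
    data_range: float = 1.0,
    win_size: int = 11,
    sigma: float = 1.5,
    k1: float = 0.01,
    k2: float = 0.03,
) -> float:
    """Mean local structural similarity with a Gaussian window.

    Standard windowed formulation: 11x11 Gaussian window (sigma 1.5),
    K1=0.01, K2=0.03, data range 1.0 by default.  Returns a value in
    [-1, 1]; identical images give exactly 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("image shape mismatch")
    if min(a.shape) < win_size:
        raise ValueError(f"images must be at least {win_size} pixels per side")
    kern = np.outer(_gaussian_kernel_1d(win_size, sigma), _gaussian_kernel_1d(win_size, sigma))

    def filt(x: np.ndarray) -> np.ndarray:
        return signal.convolve2d(x, kern, mode="valid")

    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    mu_a = filt(a)
    mu_b = filt(b)
    mu_aa = mu_a * mu_a
    mu_bb = mu_b * mu_b
    mu_ab = mu_a * mu_b
    # unbiased local (co)variances, matching the reference implementation
    np_ = win_size * win_size
    cov_norm = np_ / (np_ - 1)
    var_a = cov_norm * (filt(a * a) - mu_aa)
    var_b = cov_norm * (filt(b * b) - mu_bb)
    cov_ab = cov_norm * (filt(a * b) - mu_ab)
    num = (2 * mu_ab + c1) * (2 * cov_ab + c2)
    den = (mu_aa + mu_bb + c1) * (var_a + var_b + c2)
    return float(np.mean(num / den))


# ---------------------------------------------------------------------------
# segmentation agreement
# ---------------------------------------------------------------------------

def dice(a: np.ndarray, b: np.ndarray, class_label: int) -> float:
    """Dice coefficient ``2|A∩B| / (|A| + |B|)`` for one class; defined as
    1.0 when the class is absent from both masks."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("mask shape mismatch")
    sa = a == class_label
    sb = b == class_label
    total = int(sa.sum()) + int(sb.sum())
    if total == 0:
        return 1.0
    return 2.0 * int(np.logical_and(sa, sb).sum()) / total


def contour_points(mask: np.ndarray, class_label: int) -> np.ndarray:
    """(row, col) coordinates of class pixels having at least one
    four-neighbor of a different class (image border counts as different)."""
    mask = np.asarray(mask)
    sel = mask == class_label
    if not sel.any():
        raise ValueError(f"class {class_label} absent from mask")
    interior = np.zeros_like(sel)
    interior[1:-1, 1:-1] = (
        sel[1:-1, 1:-1]
        & sel[:-2, 1:-1]
        & sel[2:, 1:-1]
        & sel[1:-1, :-2]
        & sel[1:-1, 2:]
    )
    boundary = sel & ~interior
    return np.argwhere(boundary)


def modified_hausdorff(a: np.ndarray, b: np.ndarray) -> float:
    """Dubuisson-Jain modified Hausdorff distance between two point sets:
    the max of the two directed mean nearest-neighbor distances."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("point sets must be non-empty")
    d2 = np.sum((a[:, None, :] - b[None, :, :]) ** 2, axis=2)
    d = np.sqrt(d2)
    return float(max(d.min(axis=1).mean(), d.min(axis=0).mean()))
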
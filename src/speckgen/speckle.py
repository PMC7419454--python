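"""Fourier-optics speckle transform with a learnable spectral window.

The speckle transform multiplies an image by i.i.d. uniform random phases,
low-passes it with a (soft) square window in the frequency domain and takes
the magnitude::

    I_sp = | IFFT2( FFT2( I * exp(j*phi) ) * W_d ) |

``W_d`` is a square window of edge length ``d`` centred on the DC bin.  The
equivalent explicit circular convolution with the window's inverse DFT is
kept as a slow verification oracle (:func:`speckle_conv_oracle`).

Smaller windows produce larger speckle grains; :func:`estimate_speckle_size`
quantifies the grain size as the FWHM of the image autocorrelation.

Conventions (fixed package-wide): coordinates are (row, col), 0-based;
angles are measured counterclockwise from the positive column axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import scipy.sparse as sp

__all__ = [
    "SpectralWindow",
    "PolarGridSpec",
    "AttentionParams",
    "SpeckleBankParams",
    "make_spectral_window",
    "spectral_window_profile",
    "spectral_window_profile_grad",
    "sample_phase_field",
    "apply_speckle",
    "speckle_conv_oracle",
    "cartesian_to_polar",
    "polar_to_cartesian",
    "channel_attention",
    "init_attention_params",
    "speckle_bank_forward",
    "estimate_speckle_size",
]

ORACLE_SIZE_LIMIT = 64


# ---------------------------------------------------------------------------
# spectral window
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpectralWindow:
    """Square low-pass window in a DC-centred spectral layout.

    ``mask`` has the DC bin at ``(H//2, W//2)`` (i.e. the ``fftshift``
    layout); :func:`apply_speckle` un-shifts it before use.
    """

    edge_length_d: float
    softness: float
    mask: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


def _centered_freq_index(n: int) -> np.ndarray:
    # integer bin offsets from DC in the fftshift layout: [-n//2, ..., n - n//2 - 1]
    return np.arange(n, dtype=float) - n // 2


def spectral_window_profile(d: float, k: np.ndarray, softness: float) -> np.ndarray:
    """1-D window profile over centred frequency indices ``k``.

    With ``softness == 0`` this is the exact indicator ``|k| <= d/2``; for
    positive softness the edge is a logistic ramp, differentiable in ``d``.
    """
    if softness == 0.0:
        return (np.abs(k) <= d / 2.0).astype(float)
    arg = np.clip((d / 2.0 - np.abs(k)) / softness, -700.0, 700.0)
    return 1.0 / (1.0 + np.exp(-arg))


def spectral_window_profile_grad(d: float, k: np.ndarray, softness: float) -> np.ndarray:
    """d(profile)/d(d) for a soft (softness > 0) 1-D window profile."""
    if softness <= 0.0:
        raise ValueError("hard window (softness=0) is not differentiable in d")
    s = spectral_window_profile(d, k, softness)
    return s * (1.0 - s) / (2.0 * softness)


def make_spectral_window(
    d: float, height: int, width: int, softness: float = 0.0
) -> SpectralWindow:
    """Build a square spectral window of edge length ``d`` (pixels).

    The mask is separable: the product of two 1-D soft-edged profiles over
    the centred row/column frequency indices.  ``d == min(height, width)``
    with softness 0 yields an all-ones (identity) filter; ``d == 1`` keeps
    only the DC bin.
    """
    if height <= 0 or width <= 0:
        raise ValueError("height and width must be positive")
    if not (0.0 < d <= min(height, width)):
        raise ValueError(
            f"edge length d={d} must lie in (0, {min(height, width)}]"
        )
    if softness < 0.0:
        raise ValueError("softness must be non-negative")
    wr = spectral_window_profile(d, _centered_freq_index(height), softness)
    wc = spectral_window_profile(d, _centered_freq_index(width), softness)
    return SpectralWindow(edge_length_d=float(d), softness=float(softness),
                          mask=np.outer(wr, wc))


# ---------------------------------------------------------------------------
# random phases and the speckle transform
# ---------------------------------------------------------------------------

def sample_phase_field(height: int, width: int, seed: int) -> np.ndarray:
    """i.i.d. Uniform[0, 2*pi) phase field; identical seed, identical field."""
    if height <= 0 or width <= 0:
        raise ValueError("height and width must be positive")
    rng = np.random.default_rng(seed)
    return rng.uniform(0.0, 2.0 * np.pi, size=(height, width))


def apply_speckle(
    image: np.ndarray, window: SpectralWindow, phases: np.ndarray
) -> np.ndarray:
    """Speckle an image through the FFT route.

    Returns ``|IFFT2(FFT2(image * exp(j*phases)) * window)|``.  Output is
    non-negative; a full-spectrum hard window makes this the identity on
    non-negative images.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != window.shape or image.shape != phases.shape:
        raise ValueError(
            f"shape mismatch: image {image.shape}, window {window.shape}, "
            f"phases {phases.shape}"
        )
    field = image * np.exp(1j * phases)
    spectrum = np.fft.fft2(field) * np.fft.ifftshift(window.mask)
    return np.abs(np.fft.ifft2(spectrum))


def speckle_conv_oracle(
    image: np.ndarray, window: SpectralWindow, phases: np.ndarray
) -> np.ndarray:
    """Direct-convolution reference for :func:`apply_speckle` (test-only).

    Computes the circular convolution of ``image * exp(j*phases)`` with the
    inverse DFT of the window via explicit summation over shifts, using
    explicitly constructed DFT matrices (independent of ``np.fft``).
    O(n^4); refuses images larger than ``ORACLE_SIZE_LIMIT``.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != window.shape or image.shape != phases.shape:
        raise ValueError("shape mismatch")
    h, w = image.shape
    if max(h, w) > ORACLE_SIZE_LIMIT:
        raise ValueError(
            f"oracle limited to {ORACLE_SIZE_LIMIT}x{ORACLE_SIZE_LIMIT} images"
        )
    # inverse DFT of the window in the native (DC-at-[0,0]) layout
    mask = np.fft.ifftshift(window.mask)
    nr = np.arange(h)
    nc = np.arange(w)
    idft_r = np.exp(2j * np.pi * np.outer(nr, nr) / h) / h
    idft_c = np.exp(2j * np.pi * np.outer(nc, nc) / w) / w
    kernel = idft_r @ mask.astype(complex) @ idft_c.T

    field = image * np.exp(1j * phases)
    out = np.empty((h, w), dtype=complex)
    for n in range(h):
        for m in range(w):
            # circular convolution: sum_{p,q} field[p,q] * kernel[(n-p)%h, (m-q)%w]
            shifted = kernel[(n - nr) % h][:, (m - nc) % w]
            out[n, m] = np.sum(field * shifted)
    return np.abs(out)


# ---------------------------------------------------------------------------
# polar <-> Cartesian warping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PolarGridSpec:
    """Sampling grid for polar resampling of a Cartesian image.

    Polar images are (n_radii, n_angles) arrays: row r holds radius
    ``r * max_radius / (n_radii - 1)``, column a holds angle
    ``2*pi * a / n_angles`` counterclockwise from the positive column axis.
    """

    center_row: float
    center_col: float
    n_radii: int
    n_angles: int
    max_radius: float

    @staticmethod
    def default(height: int, width: int) -> "PolarGridSpec":
        return PolarGridSpec(
            center_row=(height - 1) / 2.0,
            center_col=(width - 1) / 2.0,
            n_radii=height,
            n_angles=width,
            max_radius=min(height, width) / 2.0,
        )

    def _validate(self, height: int, width: int) -> None:
        if self.n_radii < 2 or self.n_angles < 1:
            raise ValueError("n_radii must be >= 2 and n_angles >= 1")
        if not (0.0 < self.max_radius <= min(height, width) / 2.0):
            raise ValueError(
                f"max_radius {self.max_radius} exceeds image bounds "
                f"(limit {min(height, width) / 2.0})"
            )


def _bilinear_matrix(
    rows: np.ndarray,
    cols: np.ndarray,
    in_shape: tuple[int, int],
    wrap_cols: bool = False,
    valid: np.ndarray | None = None,
) -> sp.csr_matrix:
    """Sparse matrix of bilinear-sampling weights.

    Maps a flattened (H, W) input to a flattened output whose pixel i samples
    the input at (rows[i], cols[i]).  Out-of-bounds samples contribute 0;
    columns optionally wrap (angle axis).  Bilinear interpolation is linear
    in the image, so warps and their adjoints reduce to this one matrix.
    """
    h, w = in_shape
    n_out = rows.size
    r0 = np.floor(rows).astype(int)
    c0 = np.floor(cols).astype(int)
    fr = rows - r0
    fc = cols - c0

    data, out_idx, in_idx = [], [], []
    out_range = np.arange(n_out)
    for dr, dc, wgt in (
        (0, 0, (1 - fr) * (1 - fc)),
        (0, 1, (1 - fr) * fc),
        (1, 0, fr * (1 - fc)),
        (1, 1, fr * fc),
    ):
        rr = r0 + dr
        cc = c0 + dc
        if wrap_cols:
            cc = cc % w
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w) & (wgt > 0)
        if valid is not None:
            ok &= valid
        data.append(wgt[ok])
        out_idx.append(out_range[ok])
        in_idx.append(rr[ok] * w + cc[ok])
    mat = sp.coo_matrix(
        (np.concatenate(data), (np.concatenate(out_idx), np.concatenate(in_idx))),
        shape=(n_out, h * w),
    )
    return mat.tocsr()


@lru_cache(maxsize=64)
def _cart_to_polar_matrix(spec: PolarGridSpec, height: int, width: int) -> sp.csr_matrix:
    spec._validate(height, width)
    radii = np.arange(spec.n_radii) * spec.max_radius / (spec.n_radii - 1)
    angles = 2.0 * np.pi * np.arange(spec.n_angles) / spec.n_angles
    rho, theta = np.meshgrid(radii, angles, indexing="ij")
    rows = (spec.center_row + rho * np.sin(theta)).ravel()
    cols = (spec.center_col + rho * np.cos(theta)).ravel()
    return _bilinear_matrix(rows, cols, (height, width))


@lru_cache(maxsize=64)
def _polar_to_cart_matrix(
    spec: PolarGridSpec, out_height: int, out_width: int
) -> sp.csr_matrix:
    spec._validate(out_height, out_width)
    rr, cc = np.meshgrid(
        np.arange(out_height, dtype=float),
        np.arange(out_width, dtype=float),
        indexing="ij",
    )
    dy = rr - spec.center_row
    dx = cc - spec.center_col
    rho = np.hypot(dy, dx)
    theta = np.mod(np.arctan2(dy, dx), 2.0 * np.pi)
    r_idx = (rho * (spec.n_radii - 1) / spec.max_radius).ravel()
    a_idx = (theta * spec.n_angles / (2.0 * np.pi)).ravel()
    inside = (rho <= spec.max_radius).ravel()
    return _bilinear_matrix(
        r_idx, a_idx, (spec.n_radii, spec.n_angles), wrap_cols=True, valid=inside
    )


def cartesian_to_polar(image: np.ndarray, spec: PolarGridSpec) -> np.ndarray:
    """Resample a Cartesian image onto a (radius, angle) grid.

    Output row r, column a bilinearly samples the input at
    ``center + radius(r) * (sin th(a), cos th(a))`` (row, col); samples
    outside the image are 0.
    """
    image = np.asarray(image, dtype=float)
    mat = _cart_to_polar_matrix(spec, *image.shape)
    return (mat @ image.ravel()).reshape(spec.n_radii, spec.n_angles)


def polar_to_cartesian(
    image: np.ndarray, spec: PolarGridSpec, out_height: int, out_width: int
) -> np.ndarray:
    """Inverse warp of :func:`cartesian_to_polar`; pixels beyond
    ``max_radius`` are 0."""
    image = np.asarray(image, dtype=float)
    if image.shape != (spec.n_radii, spec.n_angles):
        raise ValueError(
            f"polar image shape {image.shape} does not match spec "
            f"({spec.n_radii}, {spec.n_angles})"
        )
    mat = _polar_to_cart_matrix(spec, out_height, out_width)
    return (mat @ image.ravel()).reshape(out_height, out_width)


# ---------------------------------------------------------------------------
# channel attention and the multi-size speckle bank
# ---------------------------------------------------------------------------

@dataclass
class AttentionParams:
    """Two-linear-layer channel attention (squeeze-excitation style):
    global sum pool -> linear -> ReLU -> linear -> sigmoid."""

    w1: np.ndarray  # (n_in, hidden)
    b1: np.ndarray  # (hidden,)
    w2: np.ndarray  # (hidden, n_out)
    b2: np.ndarray  # (n_out,)


def init_attention_params(
    n_in: int = 8, n_out: int = 32, hidden: int = 8, seed: int = 0
) -> AttentionParams:
    rng = np.random.default_rng(seed)
    return AttentionParams(
        w1=rng.normal(0.0, 1.0 / np.sqrt(n_in), (n_in, hidden)),
        b1=np.zeros(hidden),
        w2=rng.normal(0.0, 1.0 / np.sqrt(hidden), (hidden, n_out)),
        b2=np.zeros(n_out),
    )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def channel_attention(features: np.ndarray, params: AttentionParams) -> np.ndarray:
    """Per-sample attention coefficients in (0, 1), shape (n, n_out)."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 4:
        raise ValueError("features must be (n, c, h, w)")
    n_in = params.w1.shape[0]
    if features.shape[1] != n_in:
        raise ValueError(
            f"expected {n_in} input channels, got {features.shape[1]}"
        )
    pooled = features.sum(axis=(2, 3))
    hidden = np.maximum(pooled @ params.w1 + params.b1, 0.0)
    return _sigmoid(hidden @ params.w2 + params.b2)


@dataclass
class SpeckleBankParams:
    """Parameters of the multi-size speckle bank.

    Each of the ``n_in`` input channels is speckled at each of the ``S``
    window sizes; output channel ``c * S + s`` carries channel ``c`` at
    window size ``window_sizes[s]``, weighted by the attention coefficient.
    """

    window_sizes: list[float]
    attention: AttentionParams
    n_in: int = 8
    softness: float = 0.5
    polar_spec: PolarGridSpec | None = None

    @property
    def n_sizes(self) -> int:
        return len(self.window_sizes)

    @property
    def n_out(self) -> int:
        return self.n_in * self.n_sizes

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.window_sizes):
            raise ValueError("window sizes must be strictly positive")
        if self.attention.w2.shape[1] != self.n_out:
            raise ValueError(
                f"attention output dim {self.attention.w2.shape[1]} "
                f"!= n_in * S = {self.n_out}"
            )


def speckle_bank_forward(
    features: np.ndarray,
    params: SpeckleBankParams,
    seed: int | None = None,
    attention_override: np.ndarray | None = None,
) -> np.ndarray:
    """Expand (n, n_in, h, w) features to (n, n_in*S, h, w) speckled maps.

    Fresh phase fields are drawn per (sample, channel, size) from a
    process-level entropy source unless ``seed`` is given.  When
    ``polar_spec`` is set, speckle is applied in the polar (rectangular)
    domain and the result warped back polar -> Cartesian.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 4 or features.shape[1] != params.n_in:
        raise ValueError(
            f"features must be (n, {params.n_in}, h, w); got {features.shape}"
        )
    n, _, h, w = features.shape
    s_count = params.n_sizes
    if attention_override is not None:
        coeff = np.asarray(attention_override, dtype=float)
    else:
        coeff = channel_attention(features, params.attention)
    if coeff.shape != (n, params.n_out):
        raise ValueError("attention coefficients have wrong shape")

    rng = np.random.default_rng(seed)
    spec = params.polar_spec
    if spec is not None:
        sp_h, sp_w = spec.n_radii, spec.n_angles
    else:
        sp_h, sp_w = h, w

    windows = [
        make_spectral_window(d, sp_h, sp_w, params.softness)
        for d in params.window_sizes
    ]
    out = np.empty((n, params.n_out, h, w), dtype=float)
    for i in range(n):
        for c in range(params.n_in):
            chan = features[i, c]
            domain = cartesian_to_polar(chan, spec) if spec is not None else chan
            for s in range(s_count):
                phases = rng.uniform(0.0, 2.0 * np.pi, size=(sp_h, sp_w))
                speckled = apply_speckle(domain, windows[s], phases)
                if spec is not None:
                    speckled = polar_to_cartesian(speckled, spec, h, w)
                out[i, c * s_count + s] = coeff[i, c * s_count + s] * speckled
    return out


# ---------------------------------------------------------------------------
# speckle grain size
# ---------------------------------------------------------------------------

def estimate_speckle_size(image: np.ndarray) -> float:
    """FWHM (pixels) of the central peak of the normalized autocorrelation.

    The circular autocorrelation of the mean-subtracted image is computed via
    the power spectrum; the full width at half maximum is measured along the
    central row and column (sub-pixel, linear interpolation) and averaged.
    """
    image = np.asarray(image, dtype=float)
    centered = image - image.mean()
    if not np.any(centered):
        raise ValueError("speckle size undefined for a constant image")
    power = np.abs(np.fft.fft2(centered)) ** 2
    acf = np.real(np.fft.ifft2(power))
    acf = np.fft.fftshift(acf / acf[0, 0])
    h, w = acf.shape
    cr, cc = h // 2, w // 2

    def half_width(profile: np.ndarray, center: int) -> float:
        # walk outward from the peak on both sides to the first 0.5 crossing
        widths = []
        for direction in (1, -1):
            prev = profile[center]
            width = 0.0
            i = center
            while True:
                j = i + direction
                if j < 0 or j >= profile.size:
                    width = abs(j - direction - center) + 0.5
                    break
                cur = profile[j]
                if cur < 0.5:
                    frac = (prev - 0.5) / (prev - cur)
                    width = abs(i - center) + frac
                    break
                prev = cur
                i = j
            widths.append(width)
        return float(sum(widths))

    return 0.5 * (half_width(acf[cr, :], cc) + half_width(acf[:, cc], cr))
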
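"""Synthetic artery masks and speckle phantoms.

Masks are built from randomly rotated, radially disturbed ellipses: an inner
contour bounds the lumen (class 0), a larger concentric disturbed ellipse
bounds the intima/media band (class 1), and everything else is
adventitia/background (class 2).  The "disturbance" is a low-order Fourier
perturbation of the ellipse radius.

Phantoms texture a mask with per-class base intensities, speckle each class
at its own window size through the polar pipeline, and add Gaussian noise,
so the whole library is exercisable without any real ultrasound data.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from . import io as sgio
from .speckle import (
    PolarGridSpec,
    apply_speckle,
    cartesian_to_polar,
    make_spectral_window,
    polar_to_cartesian,
)

__all__ = [
    "ArteryMaskSpec",
    "PhantomTextureSpec",
    "sample_artery_mask",
    "render_phantom",
    "generate_dataset",
    "validate_mask_topology",
]

_RETRY_CAP = 50


@dataclass(frozen=True)
class ArteryMaskSpec:
    """Geometry sampler for artificial artery masks."""

    image_size: int = 256
    lumen_radius_range: tuple[float, float] = (25.0, 50.0)
    wall_thickness_range: tuple[float, float] = (12.0, 30.0)
    center_jitter: float = 12.0
    eccentricity_range: tuple[float, float] = (0.0, 0.5)
    n_harmonics: int = 4
    perturb_amp: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if (
            self.lumen_radius_range[1]
            + self.wall_thickness_range[1]
            + self.center_jitter
            >= self.image_size / 2
        ):
            raise ValueError(
                "lumen radius + wall thickness + jitter must stay below "
                "image_size / 2"
            )
        if not (0.0 <= self.perturb_amp < 1.0):
            raise ValueError("perturb_amp must lie in [0, 1)")
        if not (0.0 <= self.eccentricity_range[0] <= self.eccentricity_range[1] < 1.0):
            raise ValueError("eccentricity range must lie in [0, 1)")

    @staticmethod
    def scaled(image_size: int, seed: int = 0) -> "ArteryMaskSpec":
        """Default geometry, ranges scaled proportionally to image size."""
        f = image_size / 256.0
        return ArteryMaskSpec(
            image_size=image_size,
            lumen_radius_range=(25.0 * f, 50.0 * f),
            wall_thickness_range=(12.0 * f, 30.0 * f),
            center_jitter=12.0 * f,
            seed=seed,
        )


@dataclass(frozen=True)
class PhantomTextureSpec:
    """Texture recipe for rendering a phantom from a mask.

    ``base_intensities[c]`` is the pre-speckle intensity of class c and
    ``window_sizes[c]`` its spectral window edge length (larger d, finer
    speckle grain).
    """

    base_intensities: tuple[float, float, float] = (0.06, 0.60, 0.35)
    window_sizes: tuple[float, float, float] = (48.0, 16.0, 24.0)
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not (0.0 <= b <= 1.0) for b in self.base_intensities):
            raise ValueError("base intensities must lie in [0, 1]")


def _perturbed_ellipse_radius(
    theta: np.ndarray,
    r0: float,
    eccentricity: float,
    rotation: float,
    amps: np.ndarray,
    phis: np.ndarray,
) -> np.ndarray:
    """Radius of a rotated, area-preserving ellipse with Fourier disturbance."""
    q = (1.0 - eccentricity**2) ** 0.25
    a, b = r0 / q, r0 * q  # semi-axes keeping area = pi * r0^2
    psi = theta - rotation
    base = a * b / np.sqrt((b * np.cos(psi)) ** 2 + (a * np.sin(psi)) ** 2)
    wobble = np.zeros_like(theta)
    for k, (amp, phi) in enumerate(zip(amps, phis), start=1):
        wobble += amp * np.cos(k * theta + phi)
    return base * (1.0 + wobble)


def sample_artery_mask(spec: ArteryMaskSpec) -> np.ndarray:
    """Draw one segmentation mask; deterministic per ``spec.seed``.

    Both contours are star-shaped about a common jittered centre and the
    outer radius is clamped to exceed the lumen radius everywhere, so the
    lumen is always a single connected component fully enclosed by the
    intima/media band.  Out-of-frame draws are resampled up to a retry cap.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    half = size / 2.0

    for _ in range(_RETRY_CAP):
        r0 = rng.uniform(*spec.lumen_radius_range)
        thickness = rng.uniform(*spec.wall_thickness_range)
        ecc_l = rng.uniform(*spec.eccentricity_range)
        ecc_w = rng.uniform(*spec.eccentricity_range)
        rot_l = rng.uniform(0.0, 2.0 * np.pi)
        rot_w = rng.uniform(0.0, 2.0 * np.pi)
        cy = (size - 1) / 2.0 + rng.uniform(-spec.center_jitter, spec.center_jitter)
        cx = (size - 1) / 2.0 + rng.uniform(-spec.center_jitter, spec.center_jitter)

        def draw_harmonics() -> tuple[np.ndarray, np.ndarray]:
            raw = rng.uniform(-1.0, 1.0, spec.n_harmonics)
            total = np.abs(raw).sum()
            if total > 0:
                raw *= spec.perturb_amp * rng.uniform(0.3, 1.0) / total
            phis = rng.uniform(0.0, 2.0 * np.pi, spec.n_harmonics)
            return raw, phis

        amps_l, phis_l = draw_harmonics()
        amps_w, phis_w = draw_harmonics()
        if spec.perturb_amp == 0.0:
            amps_l = np.zeros(spec.n_harmonics)
            amps_w = np.zeros(spec.n_harmonics)

        rows, cols = np.meshgrid(
            np.arange(size, dtype=float), np.arange(size, dtype=float), indexing="ij"
        )
        dy, dx = rows - cy, cols - cx
        rho = np.hypot(dy, dx)
        theta = np.arctan2(dy, dx)

        r_lumen = _perturbed_ellipse_radius(theta, r0, ecc_l, rot_l, amps_l, phis_l)
        r_outer_raw = _perturbed_ellipse_radius(
            theta, r0 + thickness, ecc_w, rot_w, amps_w, phis_w
        )
        r_outer = np.maximum(r_outer_raw, r_lumen + 1.5)

        margin = max(abs(cy - (size - 1) / 2.0), abs(cx - (size - 1) / 2.0))
        if r_outer.max() + margin >= half - 1.0:
            continue

        mask = np.full((size, size), 2, dtype=np.int64)
        mask[rho < r_outer] = 1
        mask[rho < r_lumen] = 0
        return mask

    raise RuntimeError(
        f"failed to sample an in-frame mask after {_RETRY_CAP} attempts; "
        "spec geometry too large for the frame"
    )


def validate_mask_topology(mask: np.ndarray) -> None:
    """Assert the SegMask invariants: labels exactly {0, 1, 2}, lumen one
    connected component, and every lumen-adjacent pixel belongs to class 1."""
    from scipy import ndimage

    labels = set(np.unique(mask))
    if labels != {0, 1, 2}:
        raise ValueError(f"mask labels {sorted(labels)} != {{0, 1, 2}}")
    lumen = mask == 0
    _, n_components = ndimage.label(lumen)
    if n_components != 1:
        raise ValueError(f"lumen has {n_components} connected components")
    dilated = ndimage.binary_dilation(lumen)
    ring = dilated & ~lumen
    if not np.all(mask[ring] == 1):
        raise ValueError("lumen is not fully enclosed by the intima/media band")


def render_phantom(mask: np.ndarray, tex: PhantomTextureSpec) -> np.ndarray:
    """Texture a mask into a speckled phantom image in [0, 1].

    A per-class base-intensity image is speckled once per class at that
    class's window size — in the polar domain, then warped back so the
    grains curve around the centre — composited by the mask, and finished
    with additive Gaussian noise, clipping at 0 and rescaling to [0, 1].
    """
    mask = np.asarray(mask)
    h, w = mask.shape
    rng = np.random.default_rng(tex.seed)
    base = np.asarray(tex.base_intensities, dtype=float)[mask]

    spec = PolarGridSpec.default(h, w)
    polar_base = cartesian_to_polar(base, spec)
    out = np.zeros((h, w), dtype=float)
    for c in range(3):
        window = make_spectral_window(
            tex.window_sizes[c], spec.n_radii, spec.n_angles, softness=0.0
        )
        phases = rng.uniform(0.0, 2.0 * np.pi, (spec.n_radii, spec.n_angles))
        speckled = apply_speckle(polar_base, window, phases)
        speckled_cart = polar_to_cartesian(speckled, spec, h, w)
        out[mask == c] = speckled_cart[mask == c]

    out += rng.normal(0.0, tex.noise_sd, out.shape)
    out = np.clip(out, 0.0, None)
    peak = out.max()
    if peak > 0:
        out = out / peak
    return out


def generate_dataset(
    n: int,
    mask_spec: ArteryMaskSpec,
    tex_spec: PhantomTextureSpec,
    out_dir: str | Path,
) -> list[dict]:
    """Write ``n`` (phantom, mask) PNG pairs plus a CSV manifest.

    Per-item seeds derive deterministically from the specs' master seeds, so
    a rerun with identical specs regenerates byte-identical files.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []
    for i in range(n):
        item_seed = int(
            np.random.SeedSequence(mask_spec.seed, spawn_key=(i,)).generate_state(1)[0]
        )
        mask = sample_artery_mask(replace(mask_spec, seed=item_seed))
        phantom = render_phantom(mask, replace(tex_spec, seed=item_seed + 1))
        mask_name = f"mask_{i:04d}.png"
        phantom_name = f"phantom_{i:04d}.png"
        sgio.write_mask(mask, out_dir / mask_name)
        sgio.write_image(phantom, out_dir / phantom_name)
        manifest.append(
            {
                "index": i,
                "phantom": phantom_name,
                "mask": mask_name,
                "seed": item_seed,
                "image_size": mask_spec.image_size,
            }
        )
    with open(out_dir / "manifest.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(manifest[0].keys()))
        writer.writeheader()
        writer.writerows(manifest)
    return manifest


def dataset_checksum(out_dir: str | Path) -> str:
    """SHA-256 over the sorted bytes of every file in a dataset directory."""
    digest = hashlib.sha256()
    for path in sorted(Path(out_dir).iterdir()):
        if path.is_file():
            digest.update(path.name.encode())
            digest.update(path.read_bytes())
    return digest.hexdigest()
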
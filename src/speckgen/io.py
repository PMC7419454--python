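"""Image and mask I/O.

Single image dialect: 8-bit grayscale PNG.  Intensities map linearly between
``uint8`` and ``[0, 1]`` (``v / 255``); segmentation masks store literal
label values {0, 1, 2}.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = ["read_image", "write_image", "read_mask", "write_mask"]

VALID_LABELS = frozenset({0, 1, 2})


def _load_gray(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with Image.open(path) as img:
        if img.mode != "L":
            raise ValueError(
                f"{path}: unsupported PNG mode {img.mode!r}; "
                "only 8-bit grayscale ('L') is accepted"
            )
        return np.asarray(img, dtype=np.uint8)


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit grayscale PNG as a float image in [0, 1]."""
    return _load_gray(path).astype(float) / 255.0


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write a float image in [0, 1] as an 8-bit grayscale PNG."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    if image.min() < -1e-9 or image.max() > 1.0 + 1e-9:
        raise ValueError("image intensities must lie in [0, 1]")
    data = np.clip(np.rint(image * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(data, mode="L").save(Path(path), format="PNG")


def read_mask(path: str | Path) -> np.ndarray:
    """Read an integer label mask; any value outside {0, 1, 2} is rejected.

    A mask missing one class entirely is accepted with a warning — class
    presence is checked by the operations that need it.
    """
    data = _load_gray(path)
    bad = set(np.unique(data)) - VALID_LABELS
    if bad:
        raise ValueError(
            f"{path}: mask contains invalid label value(s) {sorted(bad)}; "
            "allowed labels are {0, 1, 2}"
        )
    missing = VALID_LABELS - set(np.unique(data))
    if missing:
        warnings.warn(f"{path}: mask is missing class(es) {sorted(missing)}")
    return data.astype(np.int64)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write an integer label mask with literal pixel values {0, 1, 2}."""
    mask = np.asarray(mask)
    bad = set(np.unique(mask)) - VALID_LABELS
    if bad:
        raise ValueError(f"mask contains invalid label value(s) {sorted(bad)}")
    Image.fromarray(mask.astype(np.uint8), mode="L").save(Path(path), format="PNG")
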
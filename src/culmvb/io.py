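"""File I/O: 8-bit grayscale images, 16-bit instance masks, CSV tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "save_image8",
    "load_image8",
    "save_mask16",
    "load_mask16",
]


def save_image8(pixels: np.ndarray, path: str | Path) -> None:
    """Write a [0, 1] float grid as an 8-bit grayscale PNG/TIFF."""
    arr = np.clip(np.asarray(pixels), 0.0, 1.0)
    Image.fromarray((arr * 255).round().astype(np.uint8)).save(path)


def load_image8(path: str | Path) -> np.ndarray:
    """Read an 8-bit grayscale image back to floats in [0, 1]."""
    return np.asarray(Image.open(path).convert("L"), dtype=np.float32) / 255.0


def save_mask16(mask: np.ndarray, path: str | Path) -> None:
    """Write an integer instance mask as a 16-bit grayscale PNG/TIFF."""
    arr = np.asarray(mask)
    if arr.min() < 0 or arr.max() > np.iinfo(np.uint16).max:
        raise ValueError("instance labels out of 16-bit range")
    Image.fromarray(arr.astype(np.uint16)).save(path)  # 16-bit grayscale


def load_mask16(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path), dtype=np.int32)
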
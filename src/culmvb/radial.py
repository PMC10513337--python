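"""Radial coordinate frame and epidermis-to-pith profiles.

Positions are expressed on the normalized radial coordinate p, running from
0 at the epidermis boundary row to 1 at the pith-cavity boundary row, so
profiles from internodes with different wall thicknesses can be aligned.
An absolute mode (pixels from the epidermis) is available for the
moving-window profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .morphometry import BundleRecord, TissueFrame

__all__ = [
    "RadialProfile",
    "build_frame",
    "area_fraction_profile",
    "count_profile",
    "moving_profile",
    "area_ratio",
]

#: intensity below which a pixel counts as tissue when framing a raw image
#: (parenchyma ~0.78, bundles ~0.38, background/cavity ~0.97)
FOREGROUND_INTENSITY = 0.88

#: default bin counts (equal width in p)
N_BINS_AREA = 20
N_BINS_COUNT = 10


@dataclass(frozen=True)
class RadialProfile:
    """Per-bin radial profile: equal-width bins on p ∈ [0, 1]."""

    bin_edges: np.ndarray
    values: np.ndarray  # area fraction or count per bin; NaN = empty bin

    @property
    def centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"p": self.centers, "value": self.values}
        )


def build_frame(source, foreground_fraction: float = 0.5) -> TissueFrame:
    """Locate the epidermis and pith boundary rows.

    From a ``GroundTruth`` the exact frame is returned. From an image (or a
    raw 2-D array) the frame spans the outermost and innermost rows whose
    fraction of tissue-intensity pixels (< FOREGROUND_INTENSITY) exceeds
    ``foreground_fraction``.
    """
    if hasattr(source, "tissue_frame"):
        return source.tissue_frame
    pixels = source.pixels if hasattr(source, "pixels") else np.asarray(source)
    fg = (pixels < FOREGROUND_INTENSITY).mean(axis=1)
    rows = np.flatnonzero(fg > foreground_fraction)
    if rows.size == 0:
        raise ValueError("no tissue rows found in image")
    return TissueFrame(epidermis_row=int(rows[0]), pith_row=int(rows[-1]) + 1)


def _row_positions(frame: TissueFrame, n_rows: int) -> np.ndarray:
    p = (np.arange(n_rows) - frame.epidermis_row) / frame.thickness
    return p


def area_fraction_profile(
    mask: np.ndarray, frame: TissueFrame, n_bins: int = N_BINS_AREA
) -> RadialProfile:
    """Bundle-pixel fraction of tissue pixels per equal-width radial bin.

    Only rows inside the tissue band contribute; a bin containing no tissue
    pixels is reported as NaN.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    mask = np.asarray(mask) > 0
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    p = _row_positions(frame, mask.shape[0])
    in_band = (p >= 0) & (p < 1)
    idx = np.clip(np.floor(p * n_bins).astype(int), 0, n_bins - 1)
    vals = np.full(n_bins, np.nan)
    W = mask.shape[1]
    row_counts = mask.sum(axis=1)
    for b in range(n_bins):
        rows = in_band & (idx == b)
        tissue = rows.sum() * W
        if tissue > 0:
            vals[b] = row_counts[rows].sum() / tissue
    return RadialProfile(bin_edges=edges, values=vals)


def count_profile(
    records: Sequence[BundleRecord], n_bins: int = N_BINS_COUNT
) -> RadialProfile:
    """Number of bundles per equal-width radial bin (by centroid position)."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    pos = np.array([r.relative_position for r in records])
    idx = np.clip(np.floor(pos * n_bins).astype(int), 0, n_bins - 1)
    vals = np.bincount(idx, minlength=n_bins).astype(float)
    return RadialProfile(bin_edges=edges, values=vals)


def moving_profile(
    records: Sequence[BundleRecord],
    window: int = 25,
    descriptor: str = "area_px",
    absolute: bool = False,
    frame: TissueFrame | None = None,
) -> pd.DataFrame:
    """Moving average ± SD of a descriptor over consecutive bundles.

    Records must be sorted by relative position. Each output point is the
    mean position, mean and population SD of exactly ``window`` consecutive
    records. With ``absolute=True`` (requires ``frame``) positions are given
    in pixels from the epidermis instead of the normalized coordinate.
    """
    n = len(records)
    if window > n:
        raise ValueError(f"window {window} exceeds record count {n}")
    pos = np.array([r.relative_position for r in records], dtype=float)
    if np.any(np.diff(pos) < 0):
        raise ValueError("records must be sorted by relative_position")
    vals = np.array([getattr(r, descriptor) for r in records], dtype=float)
    if absolute:
        if frame is None:
            raise ValueError("absolute positions require a TissueFrame")
        pos = pos * frame.thickness

    kernel = np.ones(window) / window
    mean_p = np.convolve(pos, kernel, mode="valid")
    mean_v = np.convolve(vals, kernel, mode="valid")
    mean_v2 = np.convolve(vals**2, kernel, mode="valid")
    sd = np.sqrt(np.maximum(mean_v2 - mean_v**2, 0.0))
    return pd.DataFrame({"p": mean_p, "mean": mean_v, "sd": sd})


def area_ratio(mask: np.ndarray, frame: TissueFrame) -> float:
    """Bundle pixels / tissue pixels over the whole culm wall band."""
    mask = np.asarray(mask) > 0
    band = mask[frame.epidermis_row: frame.pith_row]
    if band.size == 0:
        raise ValueError("tissue band contains no pixels")
    return float(band.mean())
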
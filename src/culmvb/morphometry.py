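"""Per-bundle morphometry computed from first principles.

Connected-component labeling, moment-based shape descriptors, convex hull
area and boundary-chain perimeter are all implemented directly on the pixel
grid rather than delegated to an image-processing library, so that every
definition used downstream (aspect = tangential bounding-box width / radial
height, extent = area / bounding-box area, eccentricity from central second
moments) is explicit and testable against independent oracles.

Conventions
-----------
* Grids are ``(row, col)`` indexed; rows run radially with row 0 on the
  epidermis side, columns tangentially.
* Bounding boxes are half-open ``(min_row, min_col, max_row, max_col)``.
* ``aspect`` is bounding-box width (tangential) divided by height (radial):
  values below 1 mean radially elongated bundles.
* ``perimeter`` is the length of the 8-connected outer boundary chain
  (axial step 1, diagonal step sqrt(2)); interior holes do not contribute.
* ``convex_area`` is the shoelace area of the convex hull of the pixel
  *corner* points, so a single pixel has convex area 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BundleRecord",
    "TissueFrame",
    "label_components",
    "measure_region",
    "measure_all",
    "relative_position",
    "records_to_frame",
]


@dataclass(frozen=True)
class TissueFrame:
    """Radial coordinate frame: epidermis row (p=0) to pith-cavity row (p=1)."""

    epidermis_row: int
    pith_row: int

    def __post_init__(self) -> None:
        if not (0 <= self.epidermis_row < self.pith_row):
            raise ValueError(
                f"degenerate tissue frame: epidermis_row={self.epidermis_row}, "
                f"pith_row={self.pith_row}"
            )

    @property
    def thickness(self) -> int:
        return self.pith_row - self.epidermis_row


@dataclass
class BundleRecord:
    """Shape descriptors of one labeled vascular bundle."""

    label: int
    area_px: int
    perimeter_px: float
    convex_area_px: float
    eccentricity: float
    aspect: float
    extent: float
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]
    touches_border: bool
    relative_position: float = float("nan")

    def as_dict(self) -> dict:
        d = asdict(self)
        d["centroid_row"], d["centroid_col"] = d.pop("centroid")
        (d["bbox_min_row"], d["bbox_min_col"],
         d["bbox_max_row"], d["bbox_max_col"]) = d.pop("bbox")
        return d


# ---------------------------------------------------------------------------
# connected components (run-based union-find)
# ---------------------------------------------------------------------------

def _find(parent: list[int], i: int) -> int:
    root = i
    while parent[root] != root:
        root = parent[root]
    while parent[i] != root:  # path compression
        parent[i], i = root, parent[i]
    return root


def label_components(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Label maximal connected components of a binary mask.

    Labels are assigned 1..K in raster-scan order of each component's first
    pixel. Uses row-run union-find; an empty mask yields an all-zero grid.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    H, W = mask.shape
    out = np.zeros((H, W), dtype=np.int32)

    parent: list[int] = []
    runs: list[tuple[int, int, int, int]] = []  # (row, start, end, run_id)
    prev: list[tuple[int, int, int]] = []  # (start, end, run_id) of previous row
    row8 = 1 if connectivity == 8 else 0

    padded = np.zeros(W + 2, dtype=np.int8)
    for r in range(H):
        padded[1:-1] = mask[r]
        d = np.diff(padded)
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        cur: list[tuple[int, int, int]] = []
        for s, e in zip(starts.tolist(), ends.tolist()):
            rid = len(parent)
            parent.append(rid)
            runs.append((r, s, e, rid))
            for ps, pe, pid in prev:
                if ps < e + row8 and pe + row8 > s:  # overlap (diag if 8-conn)
                    ra, rb = _find(parent, rid), _find(parent, pid)
                    if ra != rb:
                        parent[max(ra, rb)] = min(ra, rb)
            cur.append((s, e, rid))
        prev = cur

    # map roots to labels in raster order of first run
    label_of: dict[int, int] = {}
    nxt = 1
    for r, s, e, rid in runs:
        root = _find(parent, rid)
        lab = label_of.get(root)
        if lab is None:
            lab = nxt
            label_of[root] = lab
            nxt += 1
        out[r, s:e] = lab
    return out


# ---------------------------------------------------------------------------
# convex hull (monotone chain) on pixel corner points
# ---------------------------------------------------------------------------

def _extreme_pixels(rows: np.ndarray, cols: np.ndarray) -> list[tuple[int, int]]:
    """Per-row column extremes and per-column row extremes of a pixel set.

    Every convex-hull vertex corner belongs to one of these pixels: a pixel
    strictly between its row's extremes has corners on or inside the segment
    joining the extreme pixels' corners (and symmetrically for columns).
    """
    pts: list[tuple[int, int]] = []
    for key, val, flip in ((rows, cols, False), (cols, rows, True)):
        order = np.argsort(key, kind="stable")
        ks, vs = key[order], val[order]
        uniq, first = np.unique(ks, return_index=True)
        bounds = list(first[1:]) + [len(ks)]
        for i, k in enumerate(uniq):
            seg = vs[first[i]: bounds[i]]
            for v in (int(seg.min()), int(seg.max())):
                pts.append((v, int(k)) if flip else (int(k), v))
    return pts


def _convex_hull_area(rows: np.ndarray, cols: np.ndarray) -> float:
    """Shoelace area of the convex hull (monotone chain) of pixel corners.

    Pixel (r, c) contributes corner points (r±0.5, c±0.5), so a single pixel
    has hull area exactly 1.
    """
    corners = {
        (r + dr, c + dc)
        for (r, c) in _extreme_pixels(rows, cols)
        for dr in (-0.5, 0.5)
        for dc in (-0.5, 0.5)
    }
    p = sorted(corners)

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower: list = []
    for q in p:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], q) <= 0:
            lower.pop()
        lower.append(q)
    upper: list = []
    for q in reversed(p):
        while len(upper) >= 2 and cross(upper[-2], upper[-1], q) <= 0:
            upper.pop()
        upper.append(q)
    hull = lower[:-1] + upper[:-1]
    area = 0.0
    for i in range(len(hull)):
        x0, y0 = hull[i]
        x1, y1 = hull[(i + 1) % len(hull)]
        area += x0 * y1 - x1 * y0
    return abs(area) / 2.0


# ---------------------------------------------------------------------------
# boundary chain perimeter (Moore neighbor tracing)
# ---------------------------------------------------------------------------

# clockwise Moore neighborhood starting north; odd indices are diagonals
_MOORE = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
_SQRT2 = math.sqrt(2.0)


def _chain_perimeter(region: np.ndarray) -> float:
    """Length of the 8-connected outer boundary chain of a region mask.

    Moore-neighbor tracing with Jacob's stopping criterion; axial steps count
    1, diagonal steps sqrt(2). Interior holes do not contribute. A single
    pixel has a degenerate (empty) chain and perimeter 0.
    """
    pad = np.pad(np.asarray(region, dtype=bool), 1)
    rr, cc = np.nonzero(pad)
    if rr.size <= 1:
        return 0.0
    cur = (int(rr[0]), int(cc[0]))  # raster-first pixel; its west is background
    prev_dir = 2  # pretend we entered moving east, so backtrack is west
    perim = 0.0
    first_move: tuple | None = None
    for _ in range(8 * rr.size + 8):
        nxt = None
        for k in range(8):
            d = (prev_dir + 5 + k) % 8  # neighbor after backtrack, clockwise
            nr, nc = cur[0] + _MOORE[d][0], cur[1] + _MOORE[d][1]
            if pad[nr, nc]:
                nxt = (nr, nc)
                break
        if nxt is None:  # isolated pixel
            return 0.0
        move = (cur, d)
        if first_move is None:
            first_move = move
        elif move == first_move:
            break
        perim += _SQRT2 if d % 2 else 1.0
        cur = nxt
        prev_dir = d
    return perim


# ---------------------------------------------------------------------------
# descriptors
# ---------------------------------------------------------------------------

def measure_region(labels: np.ndarray, label: int) -> BundleRecord:
    """Compute all shape descriptors for one labeled region.

    ``relative_position`` is left NaN; attach it with :func:`relative_position`
    once a :class:`TissueFrame` is known.
    """
    labels = np.asarray(labels)
    rows, cols = np.nonzero(labels == label)
    if rows.size == 0:
        raise ValueError(f"label {label} not present in label grid")

    area = int(rows.size)
    cr = float(rows.mean())
    cc = float(cols.mean())

    # central second moments (per-pixel, normalized by area)
    dr = rows - cr
    dc = cols - cc
    mu20 = float((dr * dr).mean())
    mu02 = float((dc * dc).mean())
    mu11 = float((dr * dc).mean())
    half = math.sqrt(4.0 * mu11 * mu11 + (mu20 - mu02) ** 2) / 2.0
    lam_max = (mu20 + mu02) / 2.0 + half
    lam_min = (mu20 + mu02) / 2.0 - half
    ecc = 0.0 if lam_max <= 0 else math.sqrt(max(0.0, 1.0 - lam_min / lam_max))

    min_r, max_r = int(rows.min()), int(rows.max()) + 1
    min_c, max_c = int(cols.min()), int(cols.max()) + 1
    bbox_h = max_r - min_r
    bbox_w = max_c - min_c
    aspect = bbox_w / bbox_h
    extent = area / (bbox_h * bbox_w)

    region = labels[min_r:max_r, min_c:max_c] == label
    perim = _chain_perimeter(region)
    convex = _convex_hull_area(rows, cols)

    H, W = labels.shape
    touches = min_r == 0 or min_c == 0 or max_r == H or max_c == W

    return BundleRecord(
        label=int(label),
        area_px=area,
        perimeter_px=perim,
        convex_area_px=convex,
        eccentricity=ecc,
        aspect=aspect,
        extent=extent,
        centroid=(cr, cc),
        bbox=(min_r, min_c, max_r, max_c),
        touches_border=touches,
    )


def relative_position(centroid: tuple[float, float], frame: TissueFrame) -> float:
    """Normalized radial position of a centroid: 0 at epidermis, 1 at pith.

    Positions outside the tissue band are clamped to [0, 1].
    """
    p = (centroid[0] - frame.epidermis_row) / frame.thickness
    return min(1.0, max(0.0, p))


def measure_all(
    labels: np.ndarray,
    frame: TissueFrame | None = None,
    exclude_border: bool = False,
) -> list[BundleRecord]:
    """Measure every labeled region; optionally drop border-clipped bundles."""
    recs = []
    for lab in range(1, int(labels.max()) + 1):
        rec = measure_region(labels, lab)
        if frame is not None:
            rec.relative_position = relative_position(rec.centroid, frame)
        if exclude_border and rec.touches_border:
            continue
        recs.append(rec)
    return recs


def records_to_frame(records: Iterable[BundleRecord]) -> pd.DataFrame:
    """One CSV-ready row per bundle (the raw-descriptor table analogue)."""
    return pd.DataFrame([r.as_dict() for r in records])
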
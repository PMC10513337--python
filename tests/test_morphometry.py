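"""Morphometry: labeling and descriptors against independent oracles."""

import numpy as np
import pytest
from scipy.spatial import ConvexHull
from skimage import measure as skm

from culmvb import morphometry as mm
from conftest import random_blob_mask


# ---------------------------------------------------------------------------
# labeling
# ---------------------------------------------------------------------------

def _flood_fill_count(mask: np.ndarray, connectivity: int) -> int:
    """Brute-force component count by BFS flood fill."""
    mask = mask.astype(bool)
    seen = np.zeros_like(mask)
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    count = 0
    H, W = mask.shape
    for r in range(H):
        for c in range(W):
            if mask[r, c] and not seen[r, c]:
                count += 1
                stack = [(r, c)]
                seen[r, c] = True
                while stack:
                    rr, cc = stack.pop()
                    for dr, dc in nbrs:
                        nr, nc = rr + dr, cc + dc
                        if 0 <= nr < H and 0 <= nc < W and mask[nr, nc] \
                                and not seen[nr, nc]:
                            seen[nr, nc] = True
                            stack.append((nr, nc))
    return count


def test_two_disjoint_squares_are_two_components():
    m = np.zeros((20, 20), bool)
    m[2:7, 2:7] = True
    m[10:15, 10:15] = True
    assert mm.label_components(m).max() == 2


def test_diagonal_touch_depends_on_connectivity():
    m = np.zeros((10, 10), bool)
    m[2:4, 2:4] = True
    m[4:6, 4:6] = True  # touches only at the corner pixel diagonal
    assert mm.label_components(m, connectivity=8).max() == 1
    assert mm.label_components(m, connectivity=4).max() == 2


@pytest.mark.parametrize("connectivity", [4, 8])
def test_labeling_matches_flood_fill_oracle(connectivity):
    rng = np.random.default_rng(0)
    for _ in range(50):
        m = rng.random((25, 25)) < 0.4
        labels = mm.label_components(m, connectivity)
        assert labels.max() == _flood_fill_count(m, connectivity)
        # labels consecutive, support equals mask
        assert set(np.unique(labels)) == set(range(labels.max() + 1)) \
            if labels.max() else True
        assert ((labels > 0) == m).all()


def test_labels_in_raster_order_of_first_pixel():
    m = np.zeros((10, 10), bool)
    m[6:9, 1:3] = True   # lower-left, but later in raster order
    m[1:3, 6:9] = True   # upper-right, first pixel earlier
    labels = mm.label_components(m)
    assert labels[1, 6] == 1
    assert labels[6, 1] == 2


def test_empty_mask_yields_zero_labels():
    assert mm.label_components(np.zeros((5, 5), bool)).max() == 0


# ---------------------------------------------------------------------------
# descriptors
# ---------------------------------------------------------------------------

def test_filled_square_descriptors():
    m = np.zeros((20, 20), int)
    m[5:15, 5:15] = 1
    r = mm.measure_region(m, 1)
    assert r.area_px == 100
    assert r.extent == 1.0
    assert r.aspect == 1.0
    assert r.eccentricity == pytest.approx(0.0, abs=1e-12)
    assert r.convex_area_px == pytest.approx(100.0)
    assert r.perimeter_px == pytest.approx(36.0)
    assert r.centroid == (9.5, 9.5)


def test_rasterized_ellipse_eccentricity():
    yy, xx = np.mgrid[-50:51, -50:51]
    m = (((xx / 40.0) ** 2 + (yy / 20.0) ** 2) <= 1).astype(int)
    r = mm.measure_region(m, 1)
    # continuous ellipse with semi-axes 40, 20: e = sqrt(1 - 1/4)
    assert r.eccentricity == pytest.approx(np.sqrt(0.75), abs=0.02)
    assert r.aspect == pytest.approx(2.0, rel=0.03)


def test_descriptors_match_independent_oracles():
    """Area/moments/bbox vs regionprops; convex hull vs Qhull; 100 blobs."""
    rng = np.random.default_rng(7)
    checked = 0
    while checked < 100:
        m = random_blob_mask(rng)
        labels = mm.label_components(m, 8)
        sk = {tuple(np.round(p.centroid, 5)): p
              for p in skm.regionprops(skm.label(m, connectivity=2))}
        for lab in range(1, labels.max() + 1):
            r = mm.measure_region(labels, lab)
            p = sk[tuple(np.round(r.centroid, 5))]
            assert r.area_px == p.area  # exact
            assert r.eccentricity == pytest.approx(p.eccentricity, abs=1e-9)
            assert r.extent == pytest.approx(p.extent, abs=1e-9)
            bb = p.bbox
            assert r.bbox == bb
            assert r.aspect == pytest.approx((bb[3] - bb[1]) / (bb[2] - bb[0]))
            rows, cols = np.nonzero(labels == lab)
            corners = np.concatenate([
                np.stack([rows + dr, cols + dc], axis=1)
                for dr in (-0.5, 0.5) for dc in (-0.5, 0.5)
            ])
            assert r.convex_area_px == pytest.approx(
                ConvexHull(corners).volume, rel=1e-9)
            checked += 1


@pytest.mark.parametrize(
    "h,w", [(10, 10), (3, 17), (6, 4), (2, 2)]
)
def test_perimeter_closed_form_rectangle(h, w):
    """Axis-aligned rectangle: chain length is 2(h-1) + 2(w-1)."""
    m = np.zeros((h + 4, w + 4), int)
    m[2:2 + h, 2:2 + w] = 1
    r = mm.measure_region(m, 1)
    assert r.perimeter_px == pytest.approx(2 * (h - 1) + 2 * (w - 1))


def test_perimeter_closed_form_diagonal_staircase():
    """One-pixel diagonal of n pixels: out-and-back chain, 2(n-1)·sqrt(2)."""
    n = 9
    m = np.zeros((n + 2, n + 2), int)
    for i in range(n):
        m[i + 1, i + 1] = 1
    r = mm.measure_region(m, 1)
    assert r.perimeter_px == pytest.approx(2 * (n - 1) * np.sqrt(2.0))


def test_perimeter_of_rasterized_circle_near_circumference():
    """Chain length of a rasterized disk approximates 2πr within a few %."""
    yy, xx = np.mgrid[-40:41, -40:41]
    m = ((xx**2 + yy**2) <= 35**2).astype(int)
    r = mm.measure_region(m, 1)
    assert r.perimeter_px == pytest.approx(2 * np.pi * 35, rel=0.06)


def test_perimeter_ignores_interior_holes():
    m = np.zeros((20, 20), int)
    m[2:18, 2:18] = 1
    solid = mm.measure_region(m, 1).perimeter_px
    m[8:12, 8:12] = 0  # carve a hole: outer chain unchanged
    holed = mm.measure_region(m, 1).perimeter_px
    assert holed == pytest.approx(solid)


def test_perimeter_close_to_freeman_estimator():
    """Sanity vs scikit-image's Freeman-weighted perimeter (different
    estimator of the same boundary, expected within a few percent)."""
    rng = np.random.default_rng(3)
    for _ in range(20):
        m = random_blob_mask(rng)
        labels = mm.label_components(m, 8)
        sk = {tuple(np.round(p.centroid, 5)): p
              for p in skm.regionprops(skm.label(m, connectivity=2))}
        for lab in range(1, labels.max() + 1):
            r = mm.measure_region(labels, lab)
            if r.area_px < 30:
                continue
            p = sk[tuple(np.round(r.centroid, 5))]
            assert r.perimeter_px == pytest.approx(p.perimeter, rel=0.06)


def test_missing_label_rejected():
    m = np.zeros((5, 5), int)
    m[1, 1] = 1
    with pytest.raises(ValueError, match="label"):
        mm.measure_region(m, 3)


# ---------------------------------------------------------------------------
# invariance properties
# ---------------------------------------------------------------------------

def _big_blob(rng):
    m = random_blob_mask(rng, shape=(80, 80), n=2)
    labels = mm.label_components(m, 8)
    sizes = [(labels == l).sum() for l in range(1, labels.max() + 1)]
    lab = int(np.argmax(sizes)) + 1
    return (labels == lab).astype(int)


def _analytic_two_ellipse_mask(scale: float, params) -> np.ndarray:
    size = int(90 * scale)
    yy, xx = np.mgrid[:size, :size]
    m = np.zeros((size, size), bool)
    for (r0, c0, a, b, th) in params:
        x, y = xx - c0 * scale, yy - r0 * scale
        u = x * np.cos(th) + y * np.sin(th)
        v = -x * np.sin(th) + y * np.cos(th)
        m |= (u / (a * scale)) ** 2 + (v / (b * scale)) ** 2 <= 1
    return m.astype(int)


def test_scale_covariance():
    """Rasterizing the same shape at 2x scale: area ×4, perimeter ×≈2,
    dimensionless descriptors unchanged."""
    rng = np.random.default_rng(21)
    for _ in range(5):
        params = [
            (rng.uniform(30, 60), rng.uniform(30, 60),
             rng.uniform(8, 16), rng.uniform(8, 16), rng.uniform(0, np.pi))
            for _ in range(2)
        ]
        params.append((params[0][0] + 5, params[0][1] + 5, 10, 10, 0))  # join
        # moderate base scale keeps the 1-px rasterization granularity small
        m1 = _analytic_two_ellipse_mask(2.0, params)
        m2 = _analytic_two_ellipse_mask(4.0, params)
        l1, l2 = mm.label_components(m1, 8), mm.label_components(m2, 8)
        big1 = int(np.argmax([(l1 == l).sum() for l in range(1, l1.max() + 1)])) + 1
        big2 = int(np.argmax([(l2 == l).sum() for l in range(1, l2.max() + 1)])) + 1
        r1 = mm.measure_region(l1, big1)
        r2 = mm.measure_region(l2, big2)
        assert r2.area_px == pytest.approx(4 * r1.area_px, rel=0.03)
        assert r2.perimeter_px == pytest.approx(2 * r1.perimeter_px, rel=0.03)
        assert r2.eccentricity == pytest.approx(r1.eccentricity, abs=0.02)
        assert r2.aspect == pytest.approx(r1.aspect, abs=0.02)
        assert r2.extent == pytest.approx(r1.extent, abs=0.02)


def test_rotation_by_90_degrees_swaps_aspect():
    rng = np.random.default_rng(22)
    for _ in range(5):
        m = _big_blob(rng)
        r1 = mm.measure_region(m, 1)
        r2 = mm.measure_region(np.rot90(m).copy(), 1)
        assert r2.aspect == pytest.approx(1.0 / r1.aspect, rel=1e-9)
        assert r2.eccentricity == pytest.approx(r1.eccentricity, abs=0.01)


def test_extent_and_convexity_bounds():
    rng = np.random.default_rng(23)
    for _ in range(20):
        m = random_blob_mask(rng, shape=(50, 50), n=3)
        labels = mm.label_components(m, 8)
        for lab in range(1, labels.max() + 1):
            r = mm.measure_region(labels, lab)
            assert 0 < r.extent <= 1.0
            assert r.convex_area_px >= r.area_px - 1e-9 or r.area_px <= 2
            assert 0.0 <= r.eccentricity < 1.0


# ---------------------------------------------------------------------------
# relative position
# ---------------------------------------------------------------------------

def test_relative_position_endpoints_and_clamping():
    frame = mm.TissueFrame(epidermis_row=10, pith_row=110)
    assert mm.relative_position((10.0, 0.0), frame) == 0.0
    assert mm.relative_position((60.0, 0.0), frame) == 0.5
    assert mm.relative_position((112.0, 0.0), frame) == 1.0  # clamped
    assert mm.relative_position((5.0, 0.0), frame) == 0.0    # clamped


def test_degenerate_frame_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        mm.TissueFrame(epidermis_row=50, pith_row=50)
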
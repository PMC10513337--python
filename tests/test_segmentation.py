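"""Segmentation: tiling, network contract, training, stitching, evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from culmvb import _nn
from culmvb import segmentation as seg
from culmvb import synthgen as sg

TINY = seg.SegConfig(tile_size=32, depth=2, base_filters=4, epochs=60,
                     batch_size=2, seed=0)


# ---------------------------------------------------------------------------
# tiling
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "shape,tile,stride,expected",
    [((512, 512), 512, 512, 1),
     ((1024, 512), 512, 512, 2),
     ((700, 700), 512, 512, 4)],
)
def test_tile_counts(shape, tile, stride, expected):
    img = np.zeros(shape, np.float32)
    tiles = seg.crop_tiles(img, np.zeros(shape, np.uint8), tile, stride)
    assert len(tiles) == expected
    for t in tiles:
        assert t.image.shape == (tile, tile)


def test_remainder_tiles_edge_aligned_never_padded():
    img = np.arange(700 * 700, dtype=np.float32).reshape(700, 700)
    tiles = seg.crop_tiles(img, np.zeros_like(img, dtype=np.uint8), 512, 512)
    # the last tile must end exactly at the image edge
    corner = tiles[-1].image
    assert corner[-1, -1] == img[-1, -1]
    assert corner[0, 0] == img[700 - 512, 700 - 512]


def test_image_smaller_than_tile_rejected():
    with pytest.raises(ValueError, match="smaller than tile"):
        seg.crop_tiles(np.zeros((100, 100)), np.zeros((100, 100)), 128, 128)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    H=hst.integers(64, 300),
    W=hst.integers(64, 300),
    tile=hst.integers(16, 64),
    stride_frac=hst.floats(0.25, 1.0),
)
def test_tile_grid_covers_image_within_bounds(H, W, tile, stride_frac):
    """Edge-aligned grid: counts follow the ceil formula, every start keeps
    the tile inside the image, and the union of tiles covers the image."""
    stride = max(1, int(tile * stride_frac))
    rows = seg._grid_starts(H, tile, stride)
    n = int(np.ceil((H - tile) / stride)) + 1
    assert len(rows) <= n
    assert rows[0] == 0 and rows[-1] == H - tile
    assert all(0 <= r <= H - tile for r in rows)
    covered = np.zeros(H, bool)
    for r in rows:
        covered[r:r + tile] = True
    assert covered.all()


# ---------------------------------------------------------------------------
# model contract
# ---------------------------------------------------------------------------

def test_output_shape_and_probability_range():
    model = seg.build_model(TINY)
    x = np.random.default_rng(0).random((2, 1, 32, 32)).astype(np.float32)
    prob = model.predict_proba(x)
    assert prob.shape == x.shape
    assert prob.min() > 0.0 and prob.max() < 1.0


def test_parameter_count_matches_layer_bookkeeping():
    cfg = seg.SegConfig(tile_size=128, depth=3, base_filters=16)
    model = seg.build_model(cfg)
    assert model.num_parameters() == seg.expected_parameter_count(cfg)
    # pinned closed-form value for the desk architecture
    assert model.num_parameters() == 535_505


def test_seeded_init_is_reproducible():
    m1 = seg.build_model(TINY)
    m2 = seg.build_model(TINY)
    for p1, p2 in zip(m1.params, m2.params):
        assert np.array_equal(p1.value, p2.value)


def test_invalid_tile_depth_combination_rejected():
    with pytest.raises(ValueError, match="divisible"):
        seg.SegConfig(tile_size=100, depth=3)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def overfit_model():
    """Model trained to convergence on a single clean tile."""
    rng = np.random.default_rng(1)
    img = np.full((32, 32), 0.78, np.float32)
    mask = np.zeros((32, 32), np.uint8)
    mask[8:20, 6:18] = 1
    mask[24:30, 22:30] = 1
    img[mask > 0] = 0.38
    img += rng.normal(0, 0.02, img.shape).astype(np.float32)
    tile = seg.TrainTile(image=img, mask=mask)
    cfg = seg.SegConfig(tile_size=32, depth=2, base_filters=4, epochs=200,
                        batch_size=1, seed=0)
    model = seg.build_model(cfg)
    model, hist = seg.train(model, [tile], cfg)
    return model, hist, tile


def test_single_tile_overfit(overfit_model):
    _, hist, _ = overfit_model
    assert hist.accuracy.iloc[-1] > 0.99
    assert hist.loss.min() <= hist.loss.iloc[0]


def test_training_deterministic_for_fixed_seed():
    rng = np.random.default_rng(2)
    tiles = []
    for _ in range(2):
        img = rng.random((32, 32)).astype(np.float32)
        mask = (rng.random((32, 32)) > 0.5).astype(np.uint8)
        tiles.append(seg.TrainTile(image=img, mask=mask))
    cfg = seg.SegConfig(tile_size=32, depth=2, base_filters=4, epochs=3,
                        batch_size=1, seed=5)
    _, h1 = seg.train(seg.build_model(cfg), tiles, cfg)
    _, h2 = seg.train(seg.build_model(cfg), tiles, cfg)
    assert np.allclose(h1.loss, h2.loss, rtol=1e-6)


def test_empty_tile_set_rejected():
    model = seg.build_model(TINY)
    with pytest.raises(ValueError, match="at least one tile"):
        seg.train(model, [], TINY)


# ---------------------------------------------------------------------------
# prediction / stitching
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def generalizing_model():
    """Model trained on varied tiles so it keys on intensity, not position."""
    rng = np.random.default_rng(4)
    tiles = []
    for _ in range(10):
        img = np.full((32, 32), 0.78, np.float32)
        mask = np.zeros((32, 32), np.uint8)
        for _ in range(int(rng.integers(1, 3))):
            r, c = rng.integers(2, 20, 2)
            h, w = rng.integers(6, 12, 2)
            mask[r:r + h, c:c + w] = 1
        img[mask > 0] = 0.38
        img += rng.normal(0, 0.03, img.shape).astype(np.float32)
        tiles.append(seg.TrainTile(image=img, mask=mask))
    cfg = seg.SegConfig(tile_size=32, depth=2, base_filters=4, epochs=120,
                        batch_size=2, seed=0)
    model = seg.build_model(cfg)
    model, hist = seg.train(model, tiles, cfg)
    return model, hist


def test_trained_model_quiet_on_background(generalizing_model):
    model, _ = generalizing_model
    bg = np.full((64, 64), 0.78, np.float32)
    pred = seg.predict(model, bg, model.config)
    assert pred.shape == bg.shape
    assert pred.mean() < 0.01


def test_threshold_of_exact_probability_map_recovers_mask():
    rng = np.random.default_rng(3)
    mask = (rng.random((20, 20)) > 0.5).astype(np.uint8)
    assert np.array_equal((mask.astype(float) >= 0.5).astype(np.uint8), mask)


@pytest.mark.parametrize("bias,expected", [(2.0, 1), (-2.0, 0)])
def test_stitching_averages_equal_tile_predictions(bias, expected):
    """A constant-output network makes every tile prediction identical, so
    overlap averaging must reproduce the single-tile value everywhere."""
    cfg = seg.SegConfig(tile_size=32, depth=2, base_filters=4, seed=0)
    model = seg.build_model(cfg)
    for p in model.params:
        p.value[...] = 0.0
    model.head.b.value[...] = bias  # probability sigmoid(bias) everywhere
    img = np.random.default_rng(0).random((48, 40)).astype(np.float32)
    stitched = seg.predict(model, img, cfg)  # 2x2 overlapping tile grid
    assert np.all(stitched == expected)
    single = seg.predict(model, img[:32, :32], cfg)
    assert np.array_equal(stitched[:32, :32], single)


def test_accuracy_equals_one_minus_hamming(overfit_model):
    model, _, tile = overfit_model
    pred = seg.predict(model, tile.image, model.config)
    ev = seg.evaluate(pred, tile.mask.astype(np.int32))
    hamming = np.mean(pred != tile.mask)
    assert ev.pixel_accuracy == pytest.approx(1.0 - hamming)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def _truth_two_squares():
    inst = np.zeros((40, 40), np.int32)
    inst[5:15, 5:15] = 1
    inst[5:15, 25:35] = 2
    return inst


def test_perfect_prediction_scores_clean():
    inst = _truth_two_squares()
    ev = seg.evaluate((inst > 0).astype(np.uint8), inst)
    assert ev.pixel_accuracy == 1.0
    assert ev.connection_errors == 0
    assert ev.missed == 0


def test_bridged_instances_count_one_connection_error():
    inst = _truth_two_squares()
    pred = (inst > 0).astype(np.uint8)
    pred[9:10, 15:25] = 1  # 1-px bridge between the two squares
    ev = seg.evaluate(pred, inst)
    assert ev.connection_errors == 1
    assert ev.missed == 0


def test_missed_instance_counted():
    inst = _truth_two_squares()
    pred = np.zeros_like(inst, np.uint8)
    pred[5:15, 5:15] = 1  # only instance 1 found
    ev = seg.evaluate(pred, inst)
    assert ev.missed == 1
    assert ev.connection_errors == 0


def test_random_prediction_on_balanced_mask_near_half():
    rng = np.random.default_rng(9)
    inst = np.zeros((200, 200), np.int32)
    inst[:100] = 1  # half bundle, half background
    pred = (rng.random((200, 200)) > 0.5).astype(np.uint8)
    ev = seg.evaluate(pred, inst)
    assert ev.pixel_accuracy == pytest.approx(0.5, abs=0.02)


def test_shape_mismatch_rejected():
    with pytest.raises(ValueError, match="shape"):
        seg.evaluate(np.zeros((4, 4), np.uint8), np.zeros((5, 5), np.int32))


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def test_model_roundtrip(tmp_path, overfit_model):
    model, _, tile = overfit_model
    path = tmp_path / "model.npz"
    seg.save_model(model, str(path))
    loaded = seg.load_model(str(path))
    x = tile.image[None, None].astype(np.float32)
    assert np.allclose(model.predict_proba(x), loaded.predict_proba(x))
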
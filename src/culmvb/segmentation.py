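"""Tile-based encoder–decoder semantic segmentation of vascular bundles.

A compact U-Net-style network (contracting path of two 3×3 convolutions plus
2×2 max-pool per level, expanding path with nearest-neighbor upsampling and
skip concatenation, final 1×1 projection to a per-pixel probability) trained
with per-pixel binary cross-entropy. Accuracy is the fraction of pixels
where the thresholded prediction matches the mask, so on held-out tiles it
equals 1 − normalized Hamming distance.

Full-image prediction tiles the image on an edge-aligned grid (remainder
tiles shifted inward, never zero-padded) and averages probabilities where
tiles overlap before thresholding.

The network is implemented in NumPy (see ``_nn``); the desk-scale default
configuration (tile 128, depth 3, 16 base filters, Adam 1e-3) is sized for
single-CPU training on synthetic sections.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd

from . import _nn
from .morphometry import label_components
from .synthgen import GroundTruth, SectionImage

__all__ = [
    "SegConfig",
    "TrainTile",
    "SegEvaluation",
    "UNet",
    "crop_tiles",
    "sample_training_tiles",
    "build_model",
    "train",
    "predict",
    "evaluate",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class SegConfig:
    tile_size: int = 128
    depth: int = 3
    base_filters: int = 16
    epochs: int = 30
    learning_rate: float = 1e-3
    batch_size: int = 4
    seed: int = 0
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.tile_size % (2**self.depth) != 0:
            raise ValueError(
                f"tile_size {self.tile_size} not divisible by 2^depth={2**self.depth}"
            )
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must be in (0, 1)")


@dataclass(frozen=True)
class TrainTile:
    image: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask tiles must share a shape")
        vals = np.unique(self.mask)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask values must be binary")


@dataclass(frozen=True)
class SegEvaluation:
    pixel_accuracy: float
    connection_errors: int
    missed: int


# ---------------------------------------------------------------------------
# tiling
# ---------------------------------------------------------------------------

def _grid_starts(length: int, tile: int, stride: int) -> list[int]:
    """Edge-aligned tile starts: regular grid, remainder tile shifted inward."""
    if length < tile:
        raise ValueError(f"image extent {length} smaller than tile {tile}")
    n = int(np.ceil((length - tile) / stride)) + 1
    starts = [min(i * stride, length - tile) for i in range(n)]
    return sorted(set(starts))


def crop_tiles(
    image, mask: np.ndarray, tile_size: int, stride: int | None = None
) -> list[TrainTile]:
    """Cut (image, mask) into tiles on an edge-aligned regular grid."""
    pixels = image.pixels if isinstance(image, SectionImage) else np.asarray(image)
    mask = (np.asarray(mask) > 0).astype(np.uint8)
    if pixels.shape != mask.shape:
        raise ValueError("image and mask must share a shape")
    stride = stride or tile_size
    if stride < 1:
        raise ValueError("stride must be >= 1")
    tiles = []
    for r in _grid_starts(pixels.shape[0], tile_size, stride):
        for c in _grid_starts(pixels.shape[1], tile_size, stride):
            tiles.append(
                TrainTile(
                    image=np.ascontiguousarray(pixels[r:r + tile_size, c:c + tile_size]),
                    mask=np.ascontiguousarray(mask[r:r + tile_size, c:c + tile_size]),
                )
            )
    return tiles


def sample_training_tiles(
    sections: list[tuple[SectionImage, GroundTruth]],
    n_tiles: int,
    tile_size: int,
    seed: int = 0,
) -> list[TrainTile]:
    """Random tile positions drawn within the tissue band of each section."""
    rng = np.random.default_rng(seed)
    tiles = []
    for i in range(n_tiles):
        img, gt = sections[i % len(sections)]
        H, W = img.pixels.shape
        fr = gt.tissue_frame
        r_lo = max(0, fr.epidermis_row - tile_size // 4)
        r_hi = min(H - tile_size, fr.pith_row - tile_size // 2)
        r = int(rng.integers(r_lo, max(r_lo + 1, r_hi + 1)))
        c = int(rng.integers(0, W - tile_size + 1))
        tiles.append(
            TrainTile(
                image=np.ascontiguousarray(img.pixels[r:r + tile_size, c:c + tile_size]),
                mask=np.ascontiguousarray(
                    (gt.instance_mask[r:r + tile_size, c:c + tile_size] > 0).astype(np.uint8)
                ),
            )
        )
    return tiles


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class UNet:
    """Encoder–decoder with skip connections, NumPy forward/backward."""

    def __init__(self, config: SegConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        d, bf = config.depth, config.base_filters
        self.enc: list[tuple[_nn.Conv3x3, _nn.Conv3x3]] = []
        c_in = 1
        for lvl in range(d):
            c = bf * 2**lvl
            self.enc.append((_nn.Conv3x3(rng, c_in, c), _nn.Conv3x3(rng, c, c)))
            c_in = c
        cb = bf * 2**d
        self.bottom = (_nn.Conv3x3(rng, c_in, cb), _nn.Conv3x3(rng, cb, cb))
        self.dec: list[tuple[_nn.Conv3x3, _nn.Conv3x3, _nn.Conv3x3]] = []
        c_up = cb
        for lvl in reversed(range(d)):
            c = bf * 2**lvl
            self.dec.append((
                _nn.Conv3x3(rng, c_up, c),        # after upsample
                _nn.Conv3x3(rng, 2 * c, c),       # after skip concat
                _nn.Conv3x3(rng, c, c),
            ))
            c_up = c
        self.head = _nn.Conv1x1(rng, c_up, 1)
        self._train_rng = rng

    @property
    def params(self) -> list[_nn.Param]:
        ps = []
        for a, b in self.enc:
            ps += a.params + b.params
        ps += self.bottom[0].params + self.bottom[1].params
        for a, b, c in self.dec:
            ps += a.params + b.params + c.params
        ps += self.head.params
        return ps

    def num_parameters(self) -> int:
        return sum(p.value.size for p in self.params)

    def forward(self, x: np.ndarray, train: bool = True):
        """x (N, 1, H, W) -> logits (N, 1, H, W), cache."""
        caches = {"enc": [], "pool": [], "skips": [], "dec": []}
        h = x.astype(_nn.F32)
        for a, b in self.enc:
            h, ca = a.forward(h, train)
            h, cb = b.forward(h, train)
            caches["enc"].append((ca, cb))
            caches["skips"].append(h)
            shape = h.shape
            h, idx = _nn.maxpool2(h)
            caches["pool"].append((idx, shape))
        h, c0 = self.bottom[0].forward(h, train)
        h, c1 = self.bottom[1].forward(h, train)
        caches["bottom"] = (c0, c1)
        for lvl, (a, b, c) in enumerate(self.dec):
            h = _nn.upsample2(h)
            h, ca = a.forward(h, train)
            skip = caches["skips"][-(lvl + 1)]
            h = np.concatenate([skip, h], axis=1)
            h, cb = b.forward(h, train)
            h, cc = c.forward(h, train)
            caches["dec"].append((ca, cb, cc))
        logits, ch = self.head.forward(h, train)
        caches["head"] = ch
        return logits, caches

    def backward(self, dlogits: np.ndarray, caches) -> None:
        d = self.head.backward(dlogits, caches["head"])
        dskips: list[np.ndarray] = []
        for lvl in reversed(range(len(self.dec))):
            a, b, c = self.dec[lvl]
            ca, cb, cc = caches["dec"][lvl]
            d = c.backward(d, cc)
            d = b.backward(d, cb)
            n_skip = d.shape[1] // 2
            dskips.append(d[:, :n_skip])
            d = d[:, n_skip:]
            d = a.backward(d, ca)
            d = _nn.upsample2_backward(d)
        d = self.bottom[1].backward(d, caches["bottom"][1])
        d = self.bottom[0].backward(d, caches["bottom"][0])
        for lvl in reversed(range(len(self.enc))):
            idx, shape = caches["pool"][lvl]
            d = _nn.maxpool2_backward(d, idx, shape)
            d = d + dskips[lvl]  # dskips[i] holds the gradient for skips[i]
            a, b = self.enc[lvl]
            d = b.backward(d, caches["enc"][lvl][1])
            d = a.backward(d, caches["enc"][lvl][0])

    def predict_proba(self, tiles: np.ndarray) -> np.ndarray:
        logits, _ = self.forward(tiles, train=False)
        return _nn.sigmoid(logits)


def build_model(config: SegConfig) -> UNet:
    """Fresh network for the given configuration (deterministic per seed)."""
    return UNet(config)


def expected_parameter_count(config: SegConfig) -> int:
    """Closed-form parameter count by layer bookkeeping (3x3 convs: 9·cin·cout+cout)."""
    d, bf = config.depth, config.base_filters

    def conv3(cin, cout):
        return 9 * cin * cout + cout

    total = 0
    cin = 1
    for lvl in range(d):
        c = bf * 2**lvl
        total += conv3(cin, c) + conv3(c, c)
        cin = c
    cb = bf * 2**d
    total += conv3(cin, cb) + conv3(cb, cb)
    cup = cb
    for lvl in reversed(range(d)):
        c = bf * 2**lvl
        total += conv3(cup, c) + conv3(2 * c, c) + conv3(c, c)
        cup = c
    total += cup * 1 + 1  # 1x1 head
    return total


# ---------------------------------------------------------------------------
# training / inference
# ---------------------------------------------------------------------------

def _stack(tiles: list[TrainTile]):
    x = np.stack([t.image for t in tiles]).astype(_nn.F32)[:, None]
    y = np.stack([t.mask for t in tiles]).astype(_nn.F32)[:, None]
    return x, y


def train(model: UNet, tiles: list[TrainTile], config: SegConfig | None = None):
    """Train in place; returns (model, history DataFrame of loss/accuracy)."""
    if not tiles:
        raise ValueError("training requires at least one tile")
    config = config or model.config
    x, y = _stack(tiles)
    opt = _nn.Adam(model.params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    n = x.shape[0]
    bs = min(config.batch_size, n)
    hist = {"epoch": [], "loss": [], "accuracy": []}
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        ep_correct = 0
        for s in range(0, n, bs):
            sel = order[s:s + bs]
            xb, yb = x[sel], y[sel]
            logits, caches = model.forward(xb, train=True)
            loss, dz, p = _nn.bce_with_logits(logits, yb)
            opt.zero_grad()
            model.backward(dz, caches)
            opt.step()
            ep_loss += loss * xb.size
            ep_correct += int(((p >= config.threshold) == (yb >= 0.5)).sum())
        hist["epoch"].append(epoch)
        hist["loss"].append(ep_loss / x.size)
        hist["accuracy"].append(ep_correct / x.size)
    return model, pd.DataFrame(hist)


def predict(model: UNet, image, config: SegConfig | None = None) -> np.ndarray:
    """Full-image binary prediction stitched from edge-aligned tiles.

    Overlapping pixels average their tile probabilities before thresholding.
    """
    config = config or model.config
    pixels = image.pixels if isinstance(image, SectionImage) else np.asarray(image)
    t = config.tile_size
    acc = np.zeros(pixels.shape, dtype=np.float64)
    cnt = np.zeros(pixels.shape, dtype=np.int32)
    rows = _grid_starts(pixels.shape[0], t, t)
    cols = _grid_starts(pixels.shape[1], t, t)
    batch, slots = [], []
    for r in rows:
        for c in cols:
            batch.append(pixels[r:r + t, c:c + t])
            slots.append((r, c))
    xb = np.stack(batch).astype(_nn.F32)[:, None]
    prob = model.predict_proba(xb)[:, 0]
    for (r, c), pr in zip(slots, prob):
        acc[r:r + t, c:c + t] += pr
        cnt[r:r + t, c:c + t] += 1
    return ((acc / cnt) >= config.threshold).astype(np.uint8)


def evaluate(
    pred: np.ndarray, truth: GroundTruth | np.ndarray, min_overlap_px: int = 10
) -> SegEvaluation:
    """Pixel accuracy plus instance-level merge/miss error counts.

    A connection (merge) error is a predicted component overlapping at least
    ``min_overlap_px`` pixels of two or more distinct ground-truth bundles;
    a miss is a ground-truth bundle with no predicted overlap at all.
    """
    inst = truth.instance_mask if isinstance(truth, GroundTruth) else np.asarray(truth)
    pred = np.asarray(pred) > 0
    if pred.shape != inst.shape:
        raise ValueError("prediction and truth shapes differ")
    acc = float((pred == (inst > 0)).mean())

    pred_labels = label_components(pred, 8)
    n_pred = int(pred_labels.max())
    n_true = int(inst.max())
    connection_errors = 0
    overlapped = np.zeros(n_true + 1, dtype=bool)
    for lab in range(1, n_pred + 1):
        covered = inst[pred_labels == lab]
        covered = covered[covered > 0]
        if covered.size:
            ids, counts = np.unique(covered, return_counts=True)
            overlapped[ids] = True
            if (counts >= min_overlap_px).sum() >= 2:
                connection_errors += 1
    missed = int(n_true - overlapped[1:].sum())
    return SegEvaluation(
        pixel_accuracy=acc, connection_errors=connection_errors, missed=missed
    )


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_model(model: UNet, path: str) -> None:
    arrays = {f"p{i}": p.value for i, p in enumerate(model.params)}
    arrays["config_json"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_model(path: str) -> UNet:
    data = np.load(path)
    cfg = SegConfig(**json.loads(bytes(data["config_json"]).decode()))
    model = UNet(cfg)
    for i, p in enumerate(model.params):
        p.value[...] = data[f"p{i}"]
    return model
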
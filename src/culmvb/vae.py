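"""Variational autoencoder over extracted bundle images and latent morphing.

Individual bundles are cropped from the instance mask about their centroids,
padded square and rescaled to a fixed input size. The VAE encodes each image
to the mean and log-variance of a diagonal Gaussian posterior, samples by
reparameterization during training, and decodes to per-pixel probabilities;
the loss is the per-image summed binary cross-entropy plus β·KL(q ‖ N(0, I)).

Morphing selects anchor bundles along the radial coordinate, encodes them to
their posterior means (no sampling, so paths are deterministic), joins the
anchors by piecewise-linear interpolation in latent space and decodes every
path point to an image frame — the developmental sequence from the compact
epidermal fiber strand to the four-lobed pith-side bundle.

Desk-scale defaults (64×64 inputs, latent 32, MLP encoder/decoder) keep
training tractable on one CPU; the same contract scales to larger inputs
and latent spaces.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi

from . import _nn
from .morphometry import BundleRecord

__all__ = [
    "VAEConfig",
    "LatentPath",
    "VAE",
    "extract_bundle_images",
    "train_vae",
    "morph",
    "select_anchors",
    "save_vae",
    "load_vae",
    "ANCHOR_POSITIONS",
]

#: default anchor positions on the radial coordinate for morphing
ANCHOR_POSITIONS = (0.01, 0.09, 0.40, 0.71, 1.00)


@dataclass(frozen=True)
class VAEConfig:
    input_size: int = 64
    latent_dim: int = 32
    hidden: int = 512
    epochs: int = 150
    learning_rate: float = 1e-3
    batch_size: int = 32
    beta: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_size & (self.input_size - 1):
            raise ValueError("input_size must be a power of 2")
        if self.latent_dim < 2:
            raise ValueError("latent_dim must be >= 2")


@dataclass(frozen=True)
class LatentPath:
    anchors: np.ndarray           # (n_anchors, latent_dim)
    positions: tuple[float, ...]  # strictly increasing radial positions
    latents: np.ndarray           # (n_frames, latent_dim) along the path
    frames: np.ndarray            # (n_frames, size, size) decoded images


# ---------------------------------------------------------------------------
# bundle image extraction
# ---------------------------------------------------------------------------

def extract_bundle_images(
    labels: np.ndarray,
    records: Sequence[BundleRecord],
    size: int = 64,
    pad_frac: float = 0.15,
) -> np.ndarray:
    """Centroid-centered square crops of each bundle, rescaled to size×size.

    Each bundle's own pixels are cropped about its centroid in a square
    window (the larger bbox side plus padding), then rescaled; the output is
    binary-valued float32 in [0, 1]. Border-touching records are skipped.
    """
    if not records:
        raise ValueError("no bundle records supplied")
    labels = np.asarray(labels)
    out = []
    for rec in records:
        if rec.touches_border:
            continue
        r0, c0, r1, c1 = rec.bbox
        side = int(np.ceil(max(r1 - r0, c1 - c0) * (1 + 2 * pad_frac)))
        side = max(side, 4)
        cr, cc = rec.centroid
        window = np.zeros((side, side), dtype=np.float32)
        wr0 = int(round(cr - (side - 1) / 2))  # window center at the centroid
        wc0 = int(round(cc - (side - 1) / 2))
        rs, re = max(wr0, 0), min(wr0 + side, labels.shape[0])
        cs, ce = max(wc0, 0), min(wc0 + side, labels.shape[1])
        window[rs - wr0: re - wr0, cs - wc0: ce - wc0] = (
            labels[rs:re, cs:ce] == rec.label
        )
        zoom = size / side
        img = ndi.zoom(window, zoom, order=1, grid_mode=True, mode="grid-constant")
        img = img[:size, :size]
        if img.shape != (size, size):
            img = np.pad(img, ((0, size - img.shape[0]), (0, size - img.shape[1])))
        out.append(np.clip(img, 0.0, 1.0))
    if not out:
        raise ValueError("all records touch the border; nothing to extract")
    return np.stack(out).astype(np.float32)


def select_anchors(
    records: Sequence[BundleRecord],
    images: np.ndarray,
    positions: Sequence[float] = ANCHOR_POSITIONS,
) -> tuple[np.ndarray, list[float]]:
    """Pick, per target position, the non-border bundle nearest to it.

    ``images`` must be aligned with the non-border subset of ``records`` in
    order (as produced by :func:`extract_bundle_images`).
    """
    inner = [r for r in records if not r.touches_border]
    if len(inner) != len(images):
        raise ValueError("images not aligned with non-border records")
    pos = np.array([r.relative_position for r in inner])
    idx = [int(np.argmin(np.abs(pos - p))) for p in positions]
    return images[idx], [float(pos[i]) for i in idx]


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class VAE:
    """MLP variational autoencoder with a diagonal Gaussian posterior."""

    def __init__(self, config: VAEConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        n = config.input_size**2
        h, L = config.hidden, config.latent_dim
        self.enc1 = _nn.Dense(rng, n, h, relu=True)
        self.enc_mu = _nn.Dense(rng, h, L)
        self.enc_lv = _nn.Dense(rng, h, L)
        self.dec1 = _nn.Dense(rng, L, h, relu=True)
        self.dec2 = _nn.Dense(rng, h, n)

    @property
    def params(self) -> list[_nn.Param]:
        return (self.enc1.params + self.enc_mu.params + self.enc_lv.params
                + self.dec1.params + self.dec2.params)

    def num_parameters(self) -> int:
        return sum(p.value.size for p in self.params)

    def encode(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and log-variance for flattened images (N, n)."""
        h, _ = self.enc1.forward(x.astype(_nn.F32), train=False)
        mu, _ = self.enc_mu.forward(h, train=False)
        lv, _ = self.enc_lv.forward(h, train=False)
        return mu, lv

    def decode(self, z: np.ndarray) -> np.ndarray:
        """Per-pixel probabilities (N, size, size) from latent vectors."""
        h, _ = self.dec1.forward(z.astype(_nn.F32), train=False)
        logits, _ = self.dec2.forward(h, train=False)
        s = self.config.input_size
        return _nn.sigmoid(logits).reshape(-1, s, s)

    def reconstruct(self, images: np.ndarray) -> np.ndarray:
        mu, _ = self.encode(images.reshape(len(images), -1))
        return self.decode(mu)

    # -- training step ------------------------------------------------------

    def _step(self, x: np.ndarray, rng: np.random.Generator, beta: float):
        N = x.shape[0]
        h1, c1 = self.enc1.forward(x, train=True)
        mu, cmu = self.enc_mu.forward(h1, train=True)
        lv, clv = self.enc_lv.forward(h1, train=True)
        lv = np.clip(lv, -8.0, 8.0)
        eps = rng.standard_normal(mu.shape).astype(_nn.F32)
        z = mu + np.exp(0.5 * lv) * eps
        h2, c2 = self.dec1.forward(z, train=True)
        logits, c3 = self.dec2.forward(h2, train=True)

        # per-image summed BCE + beta * KL, averaged over the batch
        bce = float(np.sum(np.logaddexp(0.0, logits) - x * logits)) / N
        kl = float(0.5 * np.sum(np.exp(lv) + mu**2 - 1.0 - lv)) / N
        loss = bce + beta * kl

        p = _nn.sigmoid(logits)
        dlogits = ((p - x) / N).astype(_nn.F32)
        dh2 = self.dec2.backward(dlogits, c3)
        dz = self.dec1.backward(dh2, c2)
        dmu = dz + (beta / N) * mu
        dlv = dz * (0.5 * np.exp(0.5 * lv) * eps) \
            + (beta / N) * 0.5 * (np.exp(lv) - 1.0)
        dh1 = self.enc_mu.backward(dmu.astype(_nn.F32), cmu)
        dh1 = dh1 + self.enc_lv.backward(dlv.astype(_nn.F32), clv)
        self.enc1.backward(dh1.astype(_nn.F32), c1)
        return loss, bce, kl


def train_vae(images: np.ndarray, config: VAEConfig):
    """Train a VAE on (N, size, size) images; returns (model, history)."""
    images = np.asarray(images, dtype=_nn.F32)
    if images.ndim != 3 or len(images) < 2:
        raise ValueError("need at least 2 images of shape (size, size)")
    if images.shape[1] != config.input_size:
        raise ValueError(
            f"images are {images.shape[1]}px, config expects {config.input_size}"
        )
    x = images.reshape(len(images), -1)
    model = VAE(config)
    opt = _nn.Adam(model.params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    n = x.shape[0]
    bs = min(config.batch_size, n)
    history = {"epoch": [], "loss": [], "bce": [], "kl": []}
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        tot = np.zeros(3)
        nb = 0
        for s in range(0, n, bs):
            xb = x[order[s:s + bs]]
            opt.zero_grad()
            loss, bce, kl = model._step(xb, rng, config.beta)
            opt.step()
            tot += (loss, bce, kl)
            nb += 1
        history["epoch"].append(epoch)
        history["loss"].append(tot[0] / nb)
        history["bce"].append(tot[1] / nb)
        history["kl"].append(tot[2] / nb)
    return model, history


def vae_loss(model: VAE, images: np.ndarray, beta: float | None = None) -> float:
    """Evaluation loss (posterior-mean reconstruction BCE + beta·KL)."""
    beta = model.config.beta if beta is None else beta
    x = np.asarray(images, dtype=_nn.F32).reshape(len(images), -1)
    mu, lv = model.encode(x)
    h, _ = model.dec1.forward(mu, train=False)
    logits, _ = model.dec2.forward(h, train=False)
    bce = float(np.sum(np.logaddexp(0.0, logits) - x * logits)) / len(x)
    kl = float(0.5 * np.sum(np.exp(lv) + mu**2 - 1.0 - lv)) / len(x)
    return bce + beta * kl


# ---------------------------------------------------------------------------
# morphing
# ---------------------------------------------------------------------------

def morph(
    model: VAE,
    anchor_images: np.ndarray,
    positions: Sequence[float],
    frames_per_segment: int = 20,
) -> LatentPath:
    """Piecewise-linear latent path through anchor posterior means.

    Frame count is segments × frames_per_segment + 1; the first and last
    frames decode the first and last anchors' posterior means exactly.
    """
    anchor_images = np.asarray(anchor_images, dtype=_nn.F32)
    if anchor_images.ndim != 3 or len(anchor_images) < 2:
        raise ValueError("need at least 2 anchors")
    positions = tuple(float(p) for p in positions)
    if len(positions) != len(anchor_images):
        raise ValueError("positions must match anchors")
    if any(b <= a for a, b in zip(positions, positions[1:])):
        raise ValueError("anchor positions must be strictly increasing")
    mu, _ = model.encode(anchor_images.reshape(len(anchor_images), -1))
    pts = []
    for i in range(len(mu) - 1):
        ts = np.linspace(0.0, 1.0, frames_per_segment + 1)[:-1]
        pts.append(mu[i][None] * (1 - ts[:, None]) + mu[i + 1][None] * ts[:, None])
    pts.append(mu[-1][None])
    latents = np.concatenate(pts, axis=0)
    frames = model.decode(latents)
    return LatentPath(
        anchors=mu, positions=positions, latents=latents, frames=frames
    )


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_vae(model: VAE, path: str) -> None:
    arrays = {f"p{i}": p.value for i, p in enumerate(model.params)}
    arrays["config_json"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_vae(path: str) -> VAE:
    data = np.load(path)
    cfg = VAEConfig(**json.loads(bytes(data["config_json"]).decode()))
    model = VAE(cfg)
    for i, p in enumerate(model.params):
        p.value[...] = data[f"p{i}"]
    return model
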
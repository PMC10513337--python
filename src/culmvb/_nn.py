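"""Minimal NumPy neural-network primitives (float32, CPU).

Hand-derived backprop for the handful of layers the package needs: 3×3
"same" convolutions via im2col, 1×1 convolutions, 2×2 max pooling, nearest
2× upsampling, dense layers, ReLU, and a fused sigmoid/binary-cross-entropy
head. Gradients of a stride-1 same-padded convolution are themselves such
convolutions (with spatially flipped, transposed kernels), so the same
im2col path serves forward and backward.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Param:
    __slots__ = ("value", "grad", "_m", "_v")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(F32)
        self.grad = np.zeros_like(self.value)
        self._m = np.zeros_like(self.value)
        self._v = np.zeros_like(self.value)


def he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(F32)


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p in self.params:
            p._m = self.b1 * p._m + (1 - self.b1) * p.grad
            p._v = self.b2 * p._v + (1 - self.b2) * p.grad**2
            p.value -= (self.lr * (p._m / b1t)
                        / (np.sqrt(p._v / b2t) + self.eps)).astype(F32)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


# ---------------------------------------------------------------------------
# convolution (3x3, stride 1, same padding)
# ---------------------------------------------------------------------------

def _im2col3(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*9) patch matrix for a same-padded 3x3 conv."""
    N, C, H, W = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    # win (N, C, H, W, 3, 3) -> rows ordered (n, h, w), columns (c, kh, kw)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N * H * W, C * 9)
    return np.ascontiguousarray(cols, dtype=F32)


class Conv3x3:
    """3x3 same-padded convolution with optional ReLU."""

    def __init__(self, rng, c_in: int, c_out: int, relu: bool = True):
        self.W = Param(he_normal(rng, (c_out, c_in * 9), c_in * 9))
        self.b = Param(np.zeros(c_out, dtype=F32))
        self.relu = relu
        self.c_in, self.c_out = c_in, c_out

    @property
    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True):
        N, C, H, Wd = x.shape
        cols = _im2col3(x)
        out = cols @ self.W.value.T + self.b.value
        out = out.reshape(N, H, Wd, self.c_out).transpose(0, 3, 1, 2)
        mask = None
        if self.relu:
            mask = out > 0
            out = out * mask
        cache = (cols, mask, (N, C, H, Wd)) if train else None
        return out, cache

    def backward(self, dout: np.ndarray, cache):
        cols, mask, (N, C, H, Wd) = cache
        if self.relu:
            dout = dout * mask
        df = dout.transpose(0, 2, 3, 1).reshape(-1, self.c_out).astype(F32)
        self.W.grad += df.T @ cols
        self.b.grad += df.sum(axis=0)
        # dx = conv(dout, flipped W^T)
        Wk = self.W.value.reshape(self.c_out, self.c_in, 3, 3)
        Wflip = Wk[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(self.c_in, -1)
        cols_d = _im2col3(dout)
        dx = cols_d @ Wflip.T
        return dx.reshape(N, H, Wd, self.c_in).transpose(0, 3, 1, 2)


class Conv1x1:
    def __init__(self, rng, c_in: int, c_out: int):
        self.W = Param(he_normal(rng, (c_out, c_in), c_in))
        self.b = Param(np.zeros(c_out, dtype=F32))
        self.c_in, self.c_out = c_in, c_out

    @property
    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True):
        N, C, H, Wd = x.shape
        xf = x.transpose(0, 2, 3, 1).reshape(-1, C)
        out = xf @ self.W.value.T + self.b.value
        out = out.reshape(N, H, Wd, self.c_out).transpose(0, 3, 1, 2)
        return out, (xf, (N, C, H, Wd)) if train else None

    def backward(self, dout: np.ndarray, cache):
        xf, (N, C, H, Wd) = cache
        df = dout.transpose(0, 2, 3, 1).reshape(-1, self.c_out).astype(F32)
        self.W.grad += df.T @ xf
        self.b.grad += df.sum(axis=0)
        dx = df @ self.W.value
        return dx.reshape(N, H, Wd, C).transpose(0, 3, 1, 2)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def maxpool2(x: np.ndarray):
    N, C, H, W = x.shape
    blocks = x.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = blocks.reshape(N, C, H // 2, W // 2, 4)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    return out, idx


def maxpool2_backward(dout: np.ndarray, idx: np.ndarray, in_shape):
    N, C, H, W = in_shape
    dflat = np.zeros((N, C, H // 2, W // 2, 4), dtype=F32)
    np.put_along_axis(dflat, idx[..., None], dout[..., None].astype(F32), axis=-1)
    dx = dflat.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return dx.reshape(N, C, H, W)


def upsample2(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=2).repeat(2, axis=3)


def upsample2_backward(dout: np.ndarray) -> np.ndarray:
    N, C, H, W = dout.shape
    return dout.reshape(N, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))


# ---------------------------------------------------------------------------
# dense
# ---------------------------------------------------------------------------

class Dense:
    def __init__(self, rng, n_in: int, n_out: int, relu: bool = False):
        self.W = Param(he_normal(rng, (n_out, n_in), n_in))
        self.b = Param(np.zeros(n_out, dtype=F32))
        self.relu = relu

    @property
    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True):
        out = x @ self.W.value.T + self.b.value
        mask = None
        if self.relu:
            mask = out > 0
            out = out * mask
        return out, (x, mask) if train else None

    def backward(self, dout: np.ndarray, cache):
        x, mask = cache
        if self.relu:
            dout = dout * mask
        self.W.grad += dout.T.astype(F32) @ x
        self.b.grad += dout.sum(axis=0).astype(F32)
        return dout @ self.W.value


# ---------------------------------------------------------------------------
# heads
# ---------------------------------------------------------------------------

def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray):
    """Mean per-pixel binary cross-entropy and its gradient wrt logits."""
    n = z.size
    loss = float(np.mean(np.logaddexp(0.0, z) - y * z))
    p = sigmoid(z)
    dz = ((p - y) / n).astype(F32)
    return loss, dz, p
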
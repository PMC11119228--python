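"""Minimal numpy neural-network primitives: im2col convolutions, dense layers, Adam.

Everything is float32, deterministic given the seed of the rng that produced the
weights and the order of the updates.  Layers are plain functions over a flat
``dict[str, ndarray]`` of parameters so that checkpoints are a single npz file.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


def im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """Unfold ``x`` (B,C,H,W) into (B, oh*ow, C*k*k) patches plus (oh, ow)."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    B, C, H, W = x.shape
    oh = (H - k) // stride + 1
    ow = (W - k) // stride + 1
    sB, sC, sH, sW = x.strides
    view = np.lib.stride_tricks.as_strided(
        x, (B, C, oh, ow, k, k), (sB, sC, sH * stride, sW * stride, sH, sW)
    )
    cols = view.transpose(0, 2, 3, 1, 4, 5).reshape(B, oh * ow, C * k * k)
    return np.ascontiguousarray(cols), oh, ow


def col2im(dcols: np.ndarray, xshape, k: int, stride: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`im2col`: scatter-add column gradients back to (B,C,H,W)."""
    B, C, H, W = xshape
    Hp, Wp = H + 2 * pad, W + 2 * pad
    oh = (Hp - k) // stride + 1
    ow = (Wp - k) // stride + 1
    d = dcols.reshape(B, oh, ow, C, k, k).transpose(0, 3, 1, 2, 4, 5)
    dx = np.zeros((B, C, Hp, Wp), dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            dx[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += d[
                :, :, :, :, i, j
            ]
    if pad:
        dx = dx[:, :, pad:-pad, pad:-pad]
    return dx


def conv_forward(x, W, b, stride=2, pad=1):
    """3x3 (or kxk) convolution.  Returns output and the cache for backward."""
    cout, cin, k, _ = W.shape
    cols, oh, ow = im2col(x, k, stride, pad)
    out = cols @ W.reshape(cout, -1).T + b
    out = out.transpose(0, 2, 1).reshape(x.shape[0], cout, oh, ow)
    return out, (cols, x.shape, W.shape, stride, pad)


def conv_backward(dout, W, cache):
    cols, xshape, wshape, stride, pad = cache
    cout = wshape[0]
    B = dout.shape[0]
    dflat = dout.reshape(B, cout, -1).transpose(0, 2, 1)  # (B, oh*ow, cout)
    dW = np.einsum("bpc,bpk->ck", dflat, cols).reshape(wshape)
    db = dflat.sum(axis=(0, 1))
    dcols = dflat @ W.reshape(cout, -1)
    dx = col2im(dcols, xshape, wshape[2], stride, pad)
    return dx, dW, db


def relu(x):
    return np.maximum(x, 0)


def relu_backward(dout, x):
    return dout * (x > 0)


def sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(z):
    z = np.asarray(z, dtype=np.float64)
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(F32)


class Adam:
    """Adam over a dict of parameters; state keyed by parameter name."""

    def __init__(self, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for name, g in grads.items():
            p = params[name]
            m = self.m.setdefault(name, np.zeros_like(p))
            v = self.v.setdefault(name, np.zeros_like(p))
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            params[name] = p - self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
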
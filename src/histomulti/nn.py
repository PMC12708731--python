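"""Small neural-network building blocks on the in-package autodiff engine.

Layers hold their parameters as `Tensor`s with ``requires_grad=True`` and are
initialised from an explicit :class:`numpy.random.Generator`, so any two
models built from the same seed are bit-identical.  Checkpoints round-trip
through ``numpy.savez`` (see :func:`save_params` / :func:`load_params`).
"""

from __future__ import annotations

import math

import numpy as np

from ._tensor import Tensor, as_tensor


class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Tensor(rng.normal(0.0, math.sqrt(1.0 / n_in), (n_in, n_out)), True)
        self.b = Tensor(np.zeros(n_out), True)

    def __call__(self, x):
        return as_tensor(x) @ self.W + self.b

    def parameters(self):
        return [self.W, self.b]


def _im2col(x: Tensor, kh: int, kw: int, stride: int, pad: int) -> Tensor:
    """Extract (kh, kw) patches with stride; returns (B, oh*ow, C*kh*kw).

    Custom primitive: the backward pass scatter-adds patch gradients back
    onto the (padded) input.
    """
    B, C, H, W = x.shape
    xd = x.data
    if pad:
        xd = np.pad(xd, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    Hp, Wp = xd.shape[2], xd.shape[3]
    oh = (Hp - kh) // stride + 1
    ow = (Wp - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xd, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (B, C, oh, ow, kh, kw)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B, oh * ow, C * kh * kw)

    def vjp(g):
        gc = g.reshape(B, oh, ow, C, kh, kw).transpose(0, 3, 1, 2, 4, 5)
        gx = np.zeros((B, C, Hp, Wp))
        for i in range(kh):
            for j in range(kw):
                gx[:, :, i : i + oh * stride : stride, j : j + ow * stride : stride] += gc[
                    :, :, :, :, i, j
                ]
        if pad:
            gx = gx[:, :, pad:-pad, pad:-pad]
        return gx

    out = Tensor._make(cols, (x,), (vjp,))
    return out, oh, ow


class Conv2d:
    """Plain 2-D convolution (cross-correlation) via im2col + matmul."""

    def __init__(self, c_in: int, c_out: int, k: int, stride: int, pad: int,
                 rng: np.random.Generator):
        fan_in = c_in * k * k
        self.W = Tensor(rng.normal(0.0, math.sqrt(1.0 / fan_in), (fan_in, c_out)), True)
        self.b = Tensor(np.zeros(c_out), True)
        self.k, self.stride, self.pad = k, stride, pad

    def __call__(self, x):
        x = as_tensor(x)
        cols, oh, ow = _im2col(x, self.k, self.k, self.stride, self.pad)
        out = cols @ self.W + self.b  # (B, oh*ow, c_out)
        B = x.shape[0]
        return out.reshape(B, oh, ow, self.W.shape[1]).transpose(0, 3, 1, 2)

    def parameters(self):
        return [self.W, self.b]


class LayerNorm:
    def __init__(self, dim: int, eps: float = 1e-6):
        self.g = Tensor(np.ones(dim), True)
        self.b = Tensor(np.zeros(dim), True)
        self.eps = eps

    def __call__(self, x):
        x = as_tensor(x)
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.g + self.b

    def parameters(self):
        return [self.g, self.b]


def dropout_mask(shape, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Inverted-dropout multiplier: 0 with prob `rate`, else 1/(1-rate)."""
    if rate == 0.0:
        return np.ones(shape)
    keep = rng.random(shape) >= rate
    return keep / (1.0 - rate)


class AdamW:
    """AdamW with decoupled weight decay; matches the usual reference update."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.01):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr: float | None = None):
        lr = self.lr if lr is None else lr
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * p.data)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def save_params(path, named_params: dict):
    np.savez(path, **{k: v.data for k, v in named_params.items()})


def load_params(path, named_params: dict):
    with np.load(path) as z:
        for k, v in named_params.items():
            v.data = z[k].astype(np.float64)
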
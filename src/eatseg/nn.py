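"""Minimal numpy engine for the fixed window-classifier architecture.

The classifier family used here is small (a few thousand weights) and fixed in
shape: a stack of strided 1D convolutions with relu, global average pooling,
one dense relu layer and a sigmoid output unit.  This module implements exactly
that family — forward, backward, Adam, binary cross-entropy with an L1 penalty
on convolution weights — on top of BLAS matmuls via im2col.  Training runs in
float32; prediction upcasts to float64 so batched and one-by-one evaluation
agree to near machine precision.

Layout conventions: batch inputs are ``(B, T, C)``; convolution weights are
stored flat as ``(C * L, F)`` with row index ``c * L + l`` (channel-major), the
same layout used by the dense whole-day evaluation in :mod:`eatseg.inference`.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Conv1D:
    """Valid (unpadded) strided 1D convolution with relu activation."""

    def __init__(self, c_in: int, c_out: int, length: int, stride: int, rng):
        fan_in = c_in * length
        self.c_in, self.c_out = c_in, c_out
        self.length, self.stride = length, stride
        # He initialization for relu units
        self.W = (
            rng.standard_normal((fan_in, c_out)) * np.sqrt(2.0 / fan_in)
        ).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)

    @property
    def n_parameters(self) -> int:
        return self.W.size + self.b.size

    def out_length(self, t_in: int) -> int:
        if t_in < self.length:
            return 0
        return (t_in - self.length) // self.stride + 1

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        # (B, T, C) -> (B, To, C*L) with column index c*L + l
        win = sliding_window_view(x, self.length, axis=1)[:, :: self.stride]
        b, to = win.shape[0], win.shape[1]
        return np.ascontiguousarray(win).reshape(b, to, self.c_in * self.length)

    def forward(self, x: np.ndarray, train: bool = False):
        col = self._im2col(x)
        z = col @ self.W.astype(col.dtype) + self.b.astype(col.dtype)
        a = relu(z)
        cache = (col, z, x.shape[1]) if train else None
        return a, cache

    def backward(self, d_a: np.ndarray, cache, need_dx: bool):
        col, z, t_in = cache
        dz = d_a * (z > 0)
        b, to, f = dz.shape
        dz2 = dz.reshape(b * to, f)
        d_w = col.reshape(b * to, -1).T @ dz2
        d_b = dz2.sum(axis=0)
        d_x = None
        if need_dx:
            dcol = (dz @ self.W.T.astype(dz.dtype)).reshape(
                b, to, self.c_in, self.length
            )
            d_x = np.zeros((b, t_in, self.c_in), dtype=dz.dtype)
            s = self.stride
            for l in range(self.length):
                d_x[:, l : l + s * to : s, :] += dcol[:, :, :, l]
        return d_x, d_w, d_b


class Dense:
    def __init__(self, n_in: int, n_out: int, rng, he: bool = True):
        scale = np.sqrt(2.0 / n_in) if he else np.sqrt(1.0 / n_in)
        self.W = (rng.standard_normal((n_in, n_out)) * scale).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    @property
    def n_parameters(self) -> int:
        return self.W.size + self.b.size

    def forward(self, x: np.ndarray):
        return x @ self.W.astype(x.dtype) + self.b.astype(x.dtype)

    def backward(self, x: np.ndarray, dz: np.ndarray):
        d_w = x.T @ dz
        d_b = dz.sum(axis=0)
        d_x = dz @ self.W.T.astype(dz.dtype)
        return d_x, d_w, d_b


class Adam:
    """Adam with the standard bias correction (beta1=0.9, beta2=0.999)."""

    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            g = g.astype(p.dtype)
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy from logits; returns (loss, dloss/dlogits).

    Uses the numerically stable form log(1 + exp(-|z|)) + max(z, 0) - z*y.
    """
    z = logits
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    grad = (sigmoid(z) - y) / z.shape[0]
    return loss, grad
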
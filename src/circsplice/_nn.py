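"""Minimal numpy neural-network engine for the dual-branch classifier.

Implements exactly the pieces the architecture needs — 1-D convolution
(valid and keras-style 'same' padding with stride), ReLU, inverted
dropout, non-overlapping max-pooling, batch normalization over a feature
vector, a dense sigmoid head, binary cross-entropy and RMSProp — with
hand-written backprop.  Parameters are float32 (computation follows the
input dtype, so float64 gradient checks work); sequence tensors are laid
out (batch, length, channels).
"""

from __future__ import annotations

import numpy as np

EPS = 1e-7


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def same_padding(length: int, width: int, stride: int) -> tuple[int, int, int]:
    """(out_length, pad_left, pad_right) for keras 'same' semantics."""
    out = -(-length // stride)  # ceil
    total = max((out - 1) * stride + width - length, 0)
    return out, total // 2, total - total // 2


def conv1d_forward(x, W, b, stride=1, padding="valid"):
    """x: (B, L, Cin); W: (w, Cin, K); returns (out, cache).

    out: (B, Lout, K) pre-activation.  The convolution is accumulated as
    a sum of w strided matmuls (one per kernel column), which avoids
    materializing im2col patch matrices.
    """
    B, L, Cin = x.shape
    w, _, K = W.shape
    if padding == "same":
        Lout, pl, pr = same_padding(L, w, stride)
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
    else:
        Lout = (L - w) // stride + 1
        pl = pr = 0
        xp = x
    win = np.lib.stride_tricks.sliding_window_view(xp, w, axis=1)  # (B, *, Cin, w)
    win = win[:, ::stride][:, :Lout]
    # reshape in native (Cin, w) order: one contiguous gather, no transpose
    cols = win.reshape(B, Lout, Cin * w)
    Wmat = W.transpose(1, 0, 2).reshape(Cin * w, K)
    # flatten to one 2-D GEMM: much faster than numpy's batched matmul
    out = (cols.reshape(-1, Cin * w) @ Wmat).reshape(B, Lout, K) + b
    cache = (cols, xp.shape, (pl, pr), x.shape, W.shape, stride, Lout)
    return out, cache


def conv1d_backward(dout, W, cache):
    """Gradients of conv1d_forward: returns (dx, dW, db)."""
    cols, xp_shape, (pl, pr), x_shape, (w, Cin, K), stride, Lout = cache
    B = dout.shape[0]
    Wmat = W.transpose(1, 0, 2).reshape(Cin * w, K)
    db = dout.sum(axis=(0, 1))
    dW = (
        (cols.reshape(-1, Cin * w).T @ dout.reshape(-1, K))
        .reshape(Cin, w, K)
        .transpose(1, 0, 2)
        .copy()
    )
    dcols = (np.ascontiguousarray(dout).reshape(-1, K) @ Wmat.T).reshape(B, Lout, Cin, w)
    dxp = np.zeros(xp_shape, dtype=dout.dtype)
    span = (Lout - 1) * stride + 1
    for j in range(w):
        # slice targets are disjoint for fixed j, so += is an exact scatter
        dxp[:, j : j + span : stride, :] += dcols[:, :, :, j]
    L = x_shape[1]
    dx = dxp[:, pl : pl + L, :]
    return dx, dW, db


def maxpool_forward(x, size: int, stride: int):
    """Non-overlapping pooling (size == stride); trailing remainder dropped."""
    assert size == stride, "only non-overlapping pooling is supported"
    B, L, C = x.shape
    n = L // size
    blocks = x[:, : n * size].reshape(B, n, size, C)
    arg = blocks.argmax(axis=2)
    out = blocks.max(axis=2)
    return out, (arg, x.shape, size)


def maxpool_backward(dout, cache):
    arg, x_shape, size = cache
    B, n, C = dout.shape
    dx = np.zeros(x_shape, dtype=dout.dtype)
    bi = np.arange(B)[:, None, None]
    ti = np.arange(n)[None, :, None]
    ci = np.arange(C)[None, None, :]
    dx[bi, ti * size + arg, ci] = dout
    return dx


def dropout_forward(x, rate: float, rng: np.random.Generator):
    if rate <= 0.0:
        return x, None
    keep = (rng.random(x.shape) >= rate).astype(x.dtype) / (1.0 - rate)
    return x * keep, keep


def dropout_backward(dout, keep):
    return dout if keep is None else dout * keep


BN_EPS = 1e-3
BN_MOMENTUM = 0.9


def batchnorm_forward(x, gamma, beta, running_mean, running_var, train: bool):
    """BN over a (B, F) feature matrix; updates running stats in place."""
    if train:
        mean = x.mean(axis=0)
        var = x.var(axis=0)
        running_mean *= BN_MOMENTUM
        running_mean += ((1 - BN_MOMENTUM) * mean).astype(running_mean.dtype)
        running_var *= BN_MOMENTUM
        running_var += ((1 - BN_MOMENTUM) * var).astype(running_var.dtype)
    else:
        mean, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + BN_EPS)
    xhat = (x - mean) * inv_std
    out = gamma * xhat + beta
    return out, (xhat, inv_std, train)


def batchnorm_backward(dout, gamma, cache):
    xhat, inv_std, train = cache
    dgamma = (dout * xhat).sum(axis=0)
    dbeta = dout.sum(axis=0)
    if not train:
        return dout * gamma * inv_std, dgamma, dbeta
    B = dout.shape[0]
    dxhat = dout * gamma
    dx = inv_std / B * (B * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0))
    return dx, dgamma, dbeta


def sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_loss(p, y):
    p = np.clip(p, EPS, 1.0 - EPS)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


class RMSProp:
    """RMSProp with keras defaults (rho 0.9, eps 1e-7)."""

    def __init__(self, params: dict, lr: float, rho: float = 0.9):
        self.lr = lr
        self.rho = rho
        self.cache = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict):
        for k, g in grads.items():
            c = self.cache[k]
            c *= self.rho
            c += (1 - self.rho) * g * g
            params[k] -= (self.lr * g / (np.sqrt(c) + EPS)).astype(params[k].dtype)
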
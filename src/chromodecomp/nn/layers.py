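"""Functional CNN primitives with explicit backward passes.

Layout is NCHW.  3x3 convolutions are stride-1, zero-padded 'same'
cross-correlations computed via im2col + BLAS matmul; their input gradient
is the full correlation with the spatially flipped, channel-transposed
kernel, and the weight gradient reuses the im2col matrix.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _im2col3(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*9) patch matrix for a padded 3x3 window."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (N, C, H, W, 3, 3)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n * h * w, c * 9)


def conv3x3_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """x (N,C,H,W), w (F,C,3,3), b (F,) -> (N,F,H,W)."""
    n, c, h, wd = x.shape
    f = w.shape[0]
    cols = _im2col3(x)
    y = cols @ w.reshape(f, c * 9).T + b
    return y.reshape(n, h, wd, f).transpose(0, 3, 1, 2)


def conv3x3_backward(x: np.ndarray, w: np.ndarray, dy: np.ndarray):
    """Returns (dx, dw, db)."""
    n, c, h, wd = x.shape
    f = w.shape[0]
    dy_flat = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(n * h * wd, f)
    db = dy_flat.sum(axis=0)
    dw = (dy_flat.T @ _im2col3(x)).reshape(f, c, 3, 3)
    # input gradient: correlate dy with the flipped, in/out-transposed kernel
    w_rot = np.ascontiguousarray(w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
    dx = conv3x3_forward(dy, w_rot, np.zeros(c, dtype=w.dtype))
    return dx, dw, db


def conv1x1_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pointwise channel mix: w (F, C)."""
    return np.einsum("fc,nchw->nfhw", w, x, optimize=True) + b[None, :, None, None]


def conv1x1_backward(x: np.ndarray, w: np.ndarray, dy: np.ndarray):
    db = dy.sum(axis=(0, 2, 3))
    dw = np.einsum("nfhw,nchw->fc", dy, x, optimize=True)
    dx = np.einsum("fc,nfhw->nchw", w, dy, optimize=True)
    return dx, dw, db


def leaky_relu_forward(x: np.ndarray, slope: float = 0.1) -> np.ndarray:
    return np.where(x > 0, x, slope * x)


def leaky_relu_backward(x: np.ndarray, dy: np.ndarray, slope: float = 0.1) -> np.ndarray:
    return np.where(x > 0, dy, slope * dy)


def avgpool2_forward(x: np.ndarray) -> np.ndarray:
    n, c, h, w = x.shape
    return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))


def avgpool2_backward(dy: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(dy, 2, axis=2), 2, axis=3) * 0.25


def upsample2_forward(x: np.ndarray) -> np.ndarray:
    """Nearest-neighbor x2."""
    return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)


def upsample2_backward(dy: np.ndarray) -> np.ndarray:
    n, c, h, w = dy.shape
    return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out
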
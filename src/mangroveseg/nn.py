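"""Minimal CNN layer primitives with explicit backward passes.

Everything operates on float32 NCHW arrays. Convolutions are stride-1
"same" via im2col/col2im; pooling is 2x2 max with argmax routing;
upsampling is nearest-neighbour x2. Each forward returns (output, cache)
and the matching backward consumes (grad_out, cache). Correctness of the
hand-written gradients is pinned by finite-difference tests.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


def he_init(rng: np.random.Generator, out_ch: int, in_ch: int, kh: int, kw: int) -> np.ndarray:
    """Kaiming-normal weights for a ReLU conv layer."""
    std = np.sqrt(2.0 / (in_ch * kh * kw))
    return rng.normal(0.0, std, size=(out_ch, in_ch, kh, kw)).astype(DTYPE)


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    n, c, h, w = x.shape
    ph, pw = kh // 2, kw // 2
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))  # (n, c, h, w, kh, kw)
    return np.ascontiguousarray(
        win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * kh * kw)
    )


def _col2im(dcols: np.ndarray, xshape: tuple, kh: int, kw: int) -> np.ndarray:
    n, c, h, w = xshape
    ph, pw = kh // 2, kw // 2
    dxp = np.zeros((n, c, h + 2 * ph, w + 2 * pw), dtype=DTYPE)
    d6 = dcols.reshape(n, h, w, c, kh, kw).transpose(0, 3, 4, 5, 1, 2)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + h, j : j + w] += d6[:, :, i, j]
    return dxp[:, :, ph : ph + h, pw : pw + w] if (ph or pw) else dxp


def conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Stride-1 same-padded convolution. w: (F, C, kh, kw), b: (F,)."""
    n, c, h, wd = x.shape
    f, _, kh, kw = w.shape
    cols = _im2col(x, kh, kw)
    out = cols @ w.reshape(f, -1).T + b
    out = out.reshape(n, h, wd, f).transpose(0, 3, 1, 2)
    return np.ascontiguousarray(out), (cols, x.shape, w)


def conv_backward(dout: np.ndarray, cache):
    cols, xshape, w = cache
    n, c, h, wd = xshape
    f, _, kh, kw = w.shape
    dmat = dout.transpose(0, 2, 3, 1).reshape(n * h * wd, f).astype(DTYPE)
    dw = (dmat.T @ cols).reshape(w.shape)
    db = dmat.sum(axis=0)
    dcols = dmat @ w.reshape(f, -1)
    dx = _col2im(dcols, xshape, kh, kw)
    return dx, dw, db


def relu_forward(x: np.ndarray):
    out = np.maximum(x, 0.0)
    return out, x > 0


def relu_backward(dout: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return dout * mask


def maxpool2_forward(x: np.ndarray):
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2 requires even spatial dims")
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = xr.reshape(n, c, h // 2, w // 2, 4)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    return np.ascontiguousarray(out), (idx, x.shape)


def maxpool2_backward(dout: np.ndarray, cache) -> np.ndarray:
    idx, (n, c, h, w) = cache
    dflat = np.zeros((n, c, h // 2, w // 2, 4), dtype=DTYPE)
    np.put_along_axis(dflat, idx[..., None], dout[..., None].astype(DTYPE), axis=-1)
    dx = dflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return np.ascontiguousarray(dx.reshape(n, c, h, w))


def upsample2_forward(x: np.ndarray):
    return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3), x.shape


def upsample2_backward(dout: np.ndarray, xshape) -> np.ndarray:
    n, c, h, w = xshape
    return dout.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)).astype(DTYPE)


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the channel axis of NCHW logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


def softmax_backward(dprobs: np.ndarray, probs: np.ndarray) -> np.ndarray:
    """d loss / d logits given d loss / d probs, per pixel over channels."""
    dot = (dprobs * probs).sum(axis=1, keepdims=True)
    return (probs * (dprobs - dot)).astype(DTYPE)


class Adam:
    """Standard Adam with bias correction, keyed by parameter name."""

    def __init__(self, param_names, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: None for k in param_names}
        self.v = {k: None for k in param_names}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k, g in grads.items():
            if self.m[k] is None:
                self.m[k] = np.zeros_like(params[k])
                self.v[k] = np.zeros_like(params[k])
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(params[k].dtype)
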
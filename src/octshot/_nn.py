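"""Minimal NumPy neural-network kernels with explicit backward passes.

Everything here operates on plain arrays in NHWC layout and returns the
caches its backward pass needs; the calling code owns parameter storage
(flat ``name -> array`` dicts) and the Adam state.  Gradients are exact
(verified against finite differences in the test suite), not approximate.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Adam",
    "relu",
    "relu_backward",
    "sigmoid",
    "dense",
    "dense_backward",
    "conv2d",
    "conv2d_backward",
    "maxpool2",
    "maxpool2_backward",
    "conv_transpose2",
    "conv_transpose2_backward",
    "bce_with_logits",
    "bce_with_logits_backward",
]


class Adam:
    """Adam optimizer over a flat dict of parameter arrays (in-place)."""

    def __init__(self, params, lr=1e-4, beta1=0.5, beta2=0.9, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for key, g in grads.items():
            m = self.m[key]
            v = self.v[key]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            update = (self.lr / bias1) * m / (np.sqrt(v / bias2) + self.eps)
            self.params[key] -= update.astype(self.params[key].dtype, copy=False)


# -- elementwise ------------------------------------------------------------


def relu(x):
    return np.maximum(x, 0.0)


def relu_backward(dout, x):
    return dout * (x > 0)


def sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# -- dense ------------------------------------------------------------------


def dense(x, W, b):
    return x @ W + b


def dense_backward(dout, x, W):
    return dout @ W.T, x.T @ dout, dout.sum(axis=0)


# -- conv 3x3 (or any odd kernel), stride 1, zero 'same' padding ------------


def conv2d(x, W, b):
    """x (B,H,W,Cin), W (kh,kw,Cin,Cout) -> out (B,H,W,Cout), cache cols."""
    batch, h, w, cin = x.shape
    kh, kw, _, cout = W.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    cols = sliding_window_view(xp, (kh, kw), axis=(1, 2))  # (B,H,W,Cin,kh,kw)
    cols = np.ascontiguousarray(cols.transpose(0, 1, 2, 4, 5, 3))  # (B,H,W,kh,kw,Cin)
    flat = cols.reshape(batch * h * w, kh * kw * cin)
    out = flat @ W.reshape(kh * kw * cin, cout) + b
    return out.reshape(batch, h, w, cout), flat


def conv2d_backward(dout, flat_cols, W, x_shape):
    batch, h, w, cin = x_shape
    kh, kw, _, cout = W.shape
    ph, pw = kh // 2, kw // 2
    dflat = dout.reshape(-1, cout)
    dW = (flat_cols.T @ dflat).reshape(W.shape)
    db = dflat.sum(axis=0)
    dcols = (dflat @ W.reshape(-1, cout).T).reshape(batch, h, w, kh, kw, cin)
    dxp = np.zeros((batch, h + 2 * ph, w + 2 * pw, cin), dtype=dout.dtype)
    for p in range(kh):
        for q in range(kw):
            dxp[:, p : p + h, q : q + w, :] += dcols[:, :, :, p, q, :]
    return dxp[:, ph : ph + h, pw : pw + w, :], dW, db


# -- 2x2 max pooling --------------------------------------------------------


def maxpool2(x):
    batch, h, w, c = x.shape
    r = x.reshape(batch, h // 2, 2, w // 2, 2, c)
    r = r.transpose(0, 1, 3, 2, 4, 5).reshape(batch, h // 2, w // 2, 4, c)
    idx = r.argmax(axis=3)
    out = np.take_along_axis(r, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
    return out, idx


def maxpool2_backward(dout, idx, x_shape):
    batch, h, w, c = x_shape
    dr = np.zeros((batch, h // 2, w // 2, 4, c), dtype=dout.dtype)
    np.put_along_axis(dr, idx[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
    dr = dr.reshape(batch, h // 2, w // 2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
    return dr.reshape(batch, h, w, c)


# -- 2x2 stride-2 transposed convolution ------------------------------------


def conv_transpose2(x, W, b):
    """x (B,H,W,Cin), W (Cin,Cout,2,2) -> (B,2H,2W,Cout)."""
    batch, h, w, cin = x.shape
    cout = W.shape[1]
    out = np.einsum("bijc,copq->bipjqo", x, W, optimize=True)
    return out.reshape(batch, 2 * h, 2 * w, cout) + b


def conv_transpose2_backward(dout, x, W):
    batch, h2, w2, cout = dout.shape
    d = dout.reshape(batch, h2 // 2, 2, w2 // 2, 2, cout)
    dx = np.einsum("bipjqo,copq->bijc", d, W, optimize=True)
    dW = np.einsum("bijc,bipjqo->copq", x, d, optimize=True)
    db = dout.sum(axis=(0, 1, 2))
    return dx, dW, db


# -- binary cross entropy on logits -----------------------------------------


def bce_with_logits(logits, labels):
    """Mean BCE, numerically stable: max(z,0) - z*y + log(1+exp(-|z|))."""
    z = logits
    return float(
        np.mean(np.maximum(z, 0.0) - z * labels + np.log1p(np.exp(-np.abs(z))))
    )


def bce_with_logits_backward(logits, labels):
    return (sigmoid(logits) - labels) / logits.size
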
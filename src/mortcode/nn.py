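"""Minimal NumPy neural-network primitives used by the certificate coder.

Implements exactly what the architecture needs — embedding lookups,
"same"-padded 2-D convolution, ReLU, global pooling, a softmax
cross-entropy head and the Adam update — with hand-written backward
passes.  Convolutions are evaluated as a sum of kernel-offset matrix
products, which keeps everything inside BLAS and is fast enough for
desk-scale training on one CPU core.  All math is float32.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def conv2d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Zero-padded "same" convolution.

    x: (B, H, W, Cin); w: (kh, kw, Cin, Cout); b: (Cout,).
    Returns (out, cache) with out of shape (B, H, W, Cout).
    """
    B, H, W, Cin = x.shape
    kh, kw, _, Cout = w.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    out = np.broadcast_to(b, (B, H, W, Cout)).astype(DTYPE).copy()
    for i in range(kh):
        for j in range(kw):
            patch = np.ascontiguousarray(xp[:, i:i + H, j:j + W, :]).reshape(-1, Cin)
            out += (patch @ w[i, j]).reshape(B, H, W, Cout)
    return out, (xp, x.shape)


def conv2d_backward(dout: np.ndarray, w: np.ndarray, cache):
    xp, xshape = cache
    B, H, W, Cin = xshape
    kh, kw, _, Cout = w.shape
    ph, pw = kh // 2, kw // 2
    dflat = dout.reshape(-1, Cout)
    dw = np.empty_like(w)
    dxp = np.zeros_like(xp)
    for i in range(kh):
        for j in range(kw):
            patch = np.ascontiguousarray(xp[:, i:i + H, j:j + W, :]).reshape(-1, Cin)
            dw[i, j] = patch.T @ dflat
            dxp[:, i:i + H, j:j + W, :] += (dflat @ w[i, j].T).reshape(B, H, W, Cin)
    db = dflat.sum(axis=0)
    dx = dxp[:, ph:ph + H, pw:pw + W, :]
    return dx, dw, db


def relu_forward(x: np.ndarray):
    out = np.maximum(x, 0.0)
    return out, x > 0


def relu_backward(dout: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return dout * mask


def global_max_pool_forward(x: np.ndarray):
    """Max over the spatial grid. x: (B, H, W, C) -> (B, C)."""
    B, H, W, C = x.shape
    flat = x.reshape(B, H * W, C)
    idx = flat.argmax(axis=1)
    out = np.take_along_axis(flat, idx[:, None, :], axis=1)[:, 0, :]
    return out, (idx, x.shape)


def global_max_pool_backward(dout: np.ndarray, cache):
    idx, (B, H, W, C) = cache
    dflat = np.zeros((B, H * W, C), dtype=dout.dtype)
    np.put_along_axis(dflat, idx[:, None, :], dout[:, None, :], axis=1)
    return dflat.reshape(B, H, W, C)


def global_mean_pool_forward(x: np.ndarray):
    B, H, W, C = x.shape
    return x.mean(axis=(1, 2)), x.shape


def global_mean_pool_backward(dout: np.ndarray, shape):
    B, H, W, C = shape
    return np.broadcast_to(dout[:, None, None, :] / (H * W), shape).astype(dout.dtype)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_loss(logits: np.ndarray, targets: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. the logits.

    targets: (B,) integer class labels.
    """
    B = logits.shape[0]
    probs = softmax(logits.astype(np.float64))
    loss = -np.log(np.clip(probs[np.arange(B), targets], 1e-12, None)).mean()
    dlogits = probs
    dlogits[np.arange(B), targets] -= 1.0
    return float(loss), (dlogits / B).astype(DTYPE)


class Adam:
    """Adam optimizer over a dict of named parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            m = self.m[k]
            v = self.v[k]
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * np.square(g)
            params[k] -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
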
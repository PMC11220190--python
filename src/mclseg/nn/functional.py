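"""Array-level forward/backward primitives for the segmentation network.

Everything operates on float32 NCHW arrays.  Each ``*_forward`` returns
``(output, cache)`` and the matching ``*_backward`` consumes that cache, so a
layer can be run several times (the labeled and unlabeled passes share the
encoder) before its gradients are accumulated.  Convolution is im2col +
BLAS matmul; bilinear resizing is expressed through a precomputed
interpolation matrix so its backward pass is just the transpose.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = [
    "conv2d_forward",
    "conv2d_backward",
    "relu_forward",
    "relu_backward",
    "maxpool2_forward",
    "maxpool2_backward",
    "upsample2_forward",
    "upsample2_backward",
    "batchnorm_forward",
    "batchnorm_backward",
    "softmax_channel",
    "softmax_backward",
]


# ---------------------------------------------------------------------------
# convolution (stride 1, same padding)


def _im2col(xp: np.ndarray, kh: int, kw: int, h: int, w: int) -> np.ndarray:
    n, c = xp.shape[:2]
    cols = np.empty((n, c, kh, kw, h, w), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i : i + h, j : j + w]
    return cols.reshape(n, c * kh * kw, h * w)


def conv2d_forward(x, weight, bias):
    """x (N,Cin,H,W), weight (Cout,Cin,kh,kw), bias (Cout,) -> same-size output."""
    n, cin, h, w = x.shape
    cout, _, kh, kw = weight.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if ph or pw else x
    cols = _im2col(xp, kh, kw, h, w)  # (N, Cin*kh*kw, H*W)
    y = (weight.reshape(cout, -1) @ cols).reshape(n, cout, h, w)
    y += bias[None, :, None, None]
    return y, (cols, weight, x.shape)


def conv2d_backward(cache, gy):
    """Returns (gx, gw, gb)."""
    cols, weight, x_shape = cache
    n, cin, h, w = x_shape
    cout, _, kh, kw = weight.shape
    ph, pw = kh // 2, kw // 2
    gy_mat = np.ascontiguousarray(gy.reshape(n, cout, h * w))
    gw = np.matmul(gy_mat, cols.transpose(0, 2, 1)).sum(axis=0).reshape(weight.shape)
    gb = gy_mat.sum(axis=(0, 2))
    gcols = np.matmul(weight.reshape(cout, -1).T, gy_mat)  # (N, Cin*kh*kw, H*W)
    gcols = gcols.reshape(n, cin, kh, kw, h, w)
    gxp = np.zeros((n, cin, h + 2 * ph, w + 2 * pw), dtype=gy.dtype)
    for i in range(kh):
        for j in range(kw):
            gxp[:, :, i : i + h, j : j + w] += gcols[:, :, i, j]
    gx = gxp[:, :, ph : ph + h, pw : pw + w] if (ph or pw) else gxp
    return gx, gw, gb


# ---------------------------------------------------------------------------
# pointwise / pooling


def relu_forward(x):
    mask = x > 0
    return x * mask, mask


def relu_backward(mask, gy):
    return gy * mask


def maxpool2_forward(x):
    """2x2 max pooling, stride 2; spatial dims must be even."""
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"spatial dims must be even for 2x2 pooling, got {h}x{w}")
    windows = (
        x.reshape(n, c, h // 2, 2, w // 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, c, h // 2, w // 2, 4)
    )
    idx = windows.argmax(axis=-1)
    y = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]
    return y, (idx, x.shape)


def maxpool2_backward(cache, gy):
    idx, x_shape = cache
    n, c, h, w = x_shape
    gwin = np.zeros((n, c, h // 2, w // 2, 4), dtype=gy.dtype)
    np.put_along_axis(gwin, idx[..., None], gy[..., None], axis=-1)
    return (
        gwin.reshape(n, c, h // 2, w // 2, 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, c, h, w)
    )


# ---------------------------------------------------------------------------
# bilinear 2x upsampling (align_corners=False), as an interpolation matrix


@lru_cache(maxsize=None)
def _interp_matrix(n_in: int) -> np.ndarray:
    n_out = 2 * n_in
    src = np.clip((np.arange(n_out) + 0.5) / 2.0 - 0.5, 0.0, n_in - 1.0)
    i0 = np.floor(src).astype(np.intp)
    frac = (src - i0).astype(np.float32)
    i1 = np.minimum(i0 + 1, n_in - 1)
    u = np.zeros((n_out, n_in), dtype=np.float32)
    u[np.arange(n_out), i0] += 1.0 - frac
    u[np.arange(n_out), i1] += frac
    return u


def upsample2_forward(x):
    n, c, h, w = x.shape
    uh, uw = _interp_matrix(h), _interp_matrix(w)
    y = uh @ x @ uw.T  # batched over (N, C)
    return y, (h, w)


def upsample2_backward(cache, gy):
    h, w = cache
    uh, uw = _interp_matrix(h), _interp_matrix(w)
    return uh.T @ gy @ uw


# ---------------------------------------------------------------------------
# batch normalization (statistics over N, H, W per channel)


def batchnorm_forward(x, gamma, beta, running_mean, running_var,
                      train: bool, momentum: float = 0.1, eps: float = 1e-5):
    if train:
        mean = x.mean(axis=(0, 2, 3))
        var = x.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
    y = gamma[None, :, None, None] * xhat + beta[None, :, None, None]
    return y.astype(x.dtype), (xhat, invstd, gamma, train)


def batchnorm_backward(cache, gy):
    """Returns (gx, ggamma, gbeta)."""
    xhat, invstd, gamma, train = cache
    ggamma = (gy * xhat).sum(axis=(0, 2, 3))
    gbeta = gy.sum(axis=(0, 2, 3))
    gxhat = gy * gamma[None, :, None, None]
    if not train:
        return gxhat * invstd[None, :, None, None], ggamma, gbeta
    m = gy.shape[0] * gy.shape[2] * gy.shape[3]
    gx = (
        invstd[None, :, None, None]
        / m
        * (
            m * gxhat
            - gxhat.sum(axis=(0, 2, 3), keepdims=True)
            - xhat * (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        )
    )
    return gx.astype(gy.dtype), ggamma, gbeta


# ---------------------------------------------------------------------------
# channel softmax


def softmax_channel(logits):
    """Softmax over axis 1 of an (N, K, H, W) logit array."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_backward(probs, gprobs):
    """dL/dlogits given dL/dprobs for a channel softmax."""
    dot = (probs * gprobs).sum(axis=1, keepdims=True)
    return probs * (gprobs - dot)
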
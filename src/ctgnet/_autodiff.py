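"""Differentiable NumPy building blocks.

The network is expressed as pure functions of a nested parameter container
(dicts/lists of arrays) traced by HIPS ``autograd``. Convolutions are written
as sums of shifted slices contracted with BLAS matmuls, which keeps both the
forward and the reverse pass inside dense linear algebra. Everything here is
deterministic given its inputs; all randomness enters through the explicit
``numpy.random.Generator`` passed to the initializers.
"""

from __future__ import annotations

import functools

import autograd.numpy as anp
import numpy as np
from autograd import value_and_grad
from autograd.extend import defvjp, primitive
from autograd.misc import flatten

__all__ = [
    "conv2d",
    "avg_pool2",
    "relu",
    "softmax",
    "group_norm",
    "bilinear_resize",
    "global_avg_pool",
    "he_conv",
    "he_dense",
    "Adam",
    "value_and_grad",
    "flatten",
]


def relu(x):
    return anp.maximum(x, 0.0)


def softmax(x, axis=-1):
    """Numerically stable softmax along ``axis``."""
    z = x - anp.max(x, axis=axis, keepdims=True)
    e = anp.exp(z)
    return e / anp.sum(e, axis=axis, keepdims=True)


def _padded(x, k, dilation):
    pad = (k // 2) * dilation
    if not pad:
        return x
    return np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))


@primitive
def _conv2d_core(x, weight, dilation):
    """Bias-free 'same' cross-correlation, stride 1, odd kernel.

    k*k shifted slices each contracted with a (Cout, Cin) matrix; fastest
    layout for the small channel counts used here.
    """
    k = weight.shape[2]
    B, C, H, W = x.shape
    xp = _padded(x, k, dilation)
    out = np.zeros((B, weight.shape[0], H * W), dtype=x.dtype)
    for dy in range(k):
        for dx in range(k):
            xs = xp[:, :, dy * dilation:dy * dilation + H,
                    dx * dilation:dx * dilation + W].reshape(B, C, H * W)
            out += np.matmul(weight[:, :, dy, dx], xs)
    return out.reshape(B, weight.shape[0], H, W)


def _conv2d_vjp_x(ans, x, weight, dilation):
    # grad w.r.t. input: same-padded correlation with the spatially flipped,
    # channel-transposed kernel (exact for stride 1, odd k, symmetric pad)
    def vjp(g):
        wt = np.ascontiguousarray(
            np.flip(weight, axis=(2, 3)).transpose(1, 0, 2, 3))
        return _conv2d_core(g, wt, dilation)
    return vjp


def _conv2d_vjp_weight(ans, x, weight, dilation):
    def vjp(g):
        k = weight.shape[2]
        B, C, H, W = x.shape
        xp = _padded(x, k, dilation)
        g2 = g.reshape(B, -1, H * W)
        dw = np.empty_like(weight)
        for dy in range(k):
            for dx in range(k):
                xs = xp[:, :, dy * dilation:dy * dilation + H,
                        dx * dilation:dx * dilation + W].reshape(B, C, H * W)
                dw[:, :, dy, dx] = np.tensordot(g2, xs, axes=([0, 2], [0, 2]))
        return dw
    return vjp


defvjp(_conv2d_core, _conv2d_vjp_x, _conv2d_vjp_weight)


def conv2d(x, weight, bias, dilation=1):
    """'Same'-padded 2-D convolution (cross-correlation).

    x: (B, Cin, H, W); weight: (Cout, Cin, k, k); bias: (Cout,). A custom
    primitive with analytic reverse rules keeps both passes in dense matmuls.
    """
    return _conv2d_core(x, weight, dilation) + anp.reshape(bias, (1, -1, 1, 1))


def avg_pool2(x):
    """2x2 average pooling with stride 2. Requires even H and W."""
    B, C, H, W = x.shape
    x = anp.reshape(x, (B, C, H // 2, 2, W // 2, 2))
    return anp.mean(x, axis=(3, 5))


def global_avg_pool(x):
    """(B, C, H, W) -> (B, C) spatial mean."""
    return anp.mean(x, axis=(2, 3))


def group_norm(x, gamma, beta, groups, eps=1e-5):
    """Group normalization over (C/G, H, W) with learnable scale/offset.

    Keeps decoder activations (and hence logits) O(1), which matters when the
    segmentation heads are trained with a pure Dice objective: an unnormalized
    decoder can drive the softmax into exact-zero float saturation, after
    which the Dice gradient for the minority class is lost irrecoverably.
    """
    B, C, H, W = x.shape
    g = x.reshape((B, groups, (C // groups) * H * W))
    mean = anp.mean(g, axis=2, keepdims=True)
    var = anp.mean((g - mean) ** 2, axis=2, keepdims=True)
    normed = ((g - mean) / anp.sqrt(var + eps)).reshape((B, C, H, W))
    return normed * anp.reshape(gamma, (1, -1, 1, 1)) \
        + anp.reshape(beta, (1, -1, 1, 1))


@functools.lru_cache(maxsize=64)
def _resize_matrix(n_out: int, n_in: int, dtype) -> np.ndarray:
    """Half-pixel-convention bilinear interpolation matrix (n_out, n_in)."""
    R = np.zeros((n_out, n_in), dtype=np.dtype(dtype))
    if n_in == 1:
        R[:, 0] = 1.0
        return R
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    w = src - lo
    R[np.arange(n_out), lo] += 1.0 - w
    R[np.arange(n_out), hi] += w
    return R


def bilinear_resize(x, out_hw):
    """Bilinear resize of the trailing two axes of ``x`` to ``out_hw``.

    Separable: y = Rh @ x @ Rw^T with constant interpolation matrices, so the
    operation is differentiable through plain matmuls.
    """
    H, W = x.shape[-2], x.shape[-1]
    Ho, Wo = out_hw
    if (H, W) == (Ho, Wo):
        return x
    dtype = "float64" if x.dtype == np.float64 else "float32"
    Rh = _resize_matrix(Ho, H, dtype)
    Rw = _resize_matrix(Wo, W, dtype)
    return anp.matmul(Rh, anp.matmul(x, Rw.T))


def he_conv(rng: np.random.Generator, c_out: int, c_in: int, k: int,
            dtype=np.float32) -> dict:
    """He-normal conv kernel + zero bias."""
    std = np.sqrt(2.0 / (c_in * k * k))
    return {
        "W": (rng.standard_normal((c_out, c_in, k, k)) * std).astype(dtype),
        "b": np.zeros(c_out, dtype=dtype),
    }


def he_dense(rng: np.random.Generator, n_out: int, n_in: int,
             dtype=np.float32) -> dict:
    std = np.sqrt(2.0 / n_in)
    return {
        "W": (rng.standard_normal((n_out, n_in)) * std).astype(dtype),
        "b": np.zeros(n_out, dtype=dtype),
    }


class Adam:
    """Adam optimizer over an arbitrary nested parameter container."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.99, eps=1e-8):
        flat, self._unflatten = flatten(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = np.zeros_like(flat)
        self.v = np.zeros_like(flat)

    def step(self, params, grads):
        flat_p, unflatten = flatten(params)
        flat_g, _ = flatten(grads)
        self.t += 1
        self.m = self.beta1 * self.m + (1.0 - self.beta1) * flat_g
        self.v = self.beta2 * self.v + (1.0 - self.beta2) * flat_g ** 2
        mhat = self.m / (1.0 - self.beta1 ** self.t)
        vhat = self.v / (1.0 - self.beta2 ** self.t)
        flat_p = flat_p - self.lr * mhat / (np.sqrt(vhat) + self.eps)
        return unflatten(flat_p.astype(flat_g.dtype))
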
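"""Fine segmentation unit.

Fuses two task-guided feature maps and decodes them into the final binary
lesion mask:

* CSM (category selection module): the per-class global features G_global are
  passed through a 1x1 transform, each class column is reweighted by its
  prediction score h_c, and the result is matrix-multiplied with a C-channel
  1x1 projection of F', yielding class-aware spatial features
  F_CSM = [Conv(G_global) ⊙ H_score^T] · Conv(F')  of depth D1.

* AKGM (anatomical knowledge guidance module): non-local self-attention whose
  query and key are multiplied by the soft gland mask, restricting similarity
  computation to anatomically plausible tissue. With Q, K (depth D') and V
  (depth D) from 1x1 convolutions of F',

      Q' = Q ⊙ M_m,  K' = K ⊙ M_m,
      S  = softmax over keys of (Q')^T K'      (N x N, row-stochastic)
      F_AKGM[j] = α · Σ_i S[j, i] · V[i] + F'[j]

  with α a learnable scalar initialized to zero, so AKGM is exactly the
  identity on F' at initialization.

F_fine = Concat[F_CSM; F_AKGM] along channels is decoded (same
bilinear-upsample + conv pattern as the coarse decoder) into a 2-channel
per-pixel softmax; channel 0 is the lesion probability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import autograd.numpy as anp
import numpy as np

from ._autodiff import bilinear_resize, conv2d, he_conv, he_dense, softmax
from .backbone import SharedFeatures
from .cls_unit import ClassPrediction


@dataclass
class FineFeatures:
    """f_fine is the channel concatenation [f_csm; f_akgm] (either may be
    absent in ablations)."""

    f_csm: Optional[np.ndarray]
    f_akgm: Optional[np.ndarray]
    f_fine: np.ndarray
    stride: int


@dataclass
class AttentionState:
    """Intermediates of one AKGM evaluation (unbatched views for inspection)."""

    q: np.ndarray
    k: np.ndarray
    v: np.ndarray
    q_masked: np.ndarray
    k_masked: np.ndarray
    s: np.ndarray
    alpha: float


def init_csm(d: int, d1: int, num_classes: int, rng: np.random.Generator,
             dtype=np.float32) -> dict:
    return {"wg": he_dense(rng, d1, d1, dtype),
            "proj": he_conv(rng, num_classes, d, 1, dtype)}


def init_akgm(d: int, rng: np.random.Generator, qk_channels: Optional[int] = None,
              dtype=np.float32) -> dict:
    dq = qk_channels if qk_channels else max(1, d // 8)
    return {"q": he_conv(rng, dq, d, 1, dtype),
            "k": he_conv(rng, dq, d, 1, dtype),
            "v": he_conv(rng, d, d, 1, dtype),
            "alpha": np.zeros((), dtype=dtype)}


def _promote(x):
    """Add a batch axis to a (C, H, W) array; report whether it was batched."""
    if np.ndim(x) == 4:
        return x, True
    return anp.reshape(x, (1,) + np.shape(x)), False


def csm(f: SharedFeatures, pred: ClassPrediction, params) -> np.ndarray:
    """Category-attention features of shape (D1, H, W) (batched accordingly)."""
    fv, batched = _promote(f.values)
    B, D, H, W = np.shape(fv)
    g = pred.g_global
    h = pred.h_score
    if np.ndim(g) == 2:
        g = anp.reshape(g, (1,) + np.shape(g))
        h = anp.reshape(h, (1,) + np.shape(h))
    C = np.shape(g)[2]
    if params["proj"]["W"].shape[0] != C:
        raise ValueError(
            f"class-count mismatch: prediction has {C} classes, CSM projection "
            f"{params['proj']['W'].shape[0]}")
    # W_g = 1x1 transform of G_global, applied to each class column
    wg = anp.matmul(params["wg"]["W"], g) + anp.reshape(params["wg"]["b"], (1, -1, 1))
    weighted = wg * anp.reshape(h, (B, 1, C))          # column c scaled by h_c
    p = conv2d(fv, params["proj"]["W"], params["proj"]["b"])   # (B, C, H, W)
    p = anp.reshape(p, (B, C, H * W))
    out = anp.matmul(weighted, p)                      # (B, D1, N)
    out = anp.reshape(out, (B, -1, H, W))
    return out if batched else out[0]


def akgm(f: SharedFeatures, m_gland, params, return_state: bool = False):
    """Gland-masked self-attention features of shape (D, H, W).

    ``m_gland`` is the soft gland mask at any resolution, (H, W) or (B, H, W);
    it is resized bilinearly to the feature grid.
    """
    fv, batched = _promote(f.values)
    B, D, H, W = np.shape(fv)
    N = H * W
    m = bilinear_resize(m_gland, (H, W))
    if np.ndim(m) == 2:
        m = anp.reshape(m, (1, 1, H, W))
    else:
        m = anp.reshape(m, (np.shape(m)[0], 1, H, W))
    q = conv2d(fv, params["q"]["W"], params["q"]["b"])
    k = conv2d(fv, params["k"]["W"], params["k"]["b"])
    v = conv2d(fv, params["v"]["W"], params["v"]["b"])
    qm = anp.reshape(q * m, (B, -1, N))
    km = anp.reshape(k * m, (B, -1, N))
    vf = anp.reshape(v, (B, D, N))
    logits = anp.matmul(anp.transpose(qm, (0, 2, 1)), km)   # (B, N, N)
    s = softmax(logits, axis=2)                             # rows sum to 1
    attended = anp.matmul(vf, anp.transpose(s, (0, 2, 1)))  # (B, D, N)
    out = params["alpha"] * anp.reshape(attended, (B, D, H, W)) + fv
    if not batched:
        out = out[0]
    if return_state:
        state = AttentionState(
            q=np.asarray(q)[0].reshape(-1, N), k=np.asarray(k)[0].reshape(-1, N),
            v=np.asarray(vf)[0], q_masked=np.asarray(qm)[0],
            k_masked=np.asarray(km)[0], s=np.asarray(s)[0],
            alpha=float(params["alpha"]))
        return out, state
    return out


def fuse(f_csm: Optional[np.ndarray], f_akgm: Optional[np.ndarray],
         stride: int) -> FineFeatures:
    """F_fine = Concat[F_CSM; F_AKGM]; either input alone in ablations."""
    parts = [x for x in (f_csm, f_akgm) if x is not None]
    if not parts:
        raise ValueError("fine segmentation needs at least one of CSM/AKGM")
    axis = 1 if np.ndim(parts[0]) == 4 else 0
    f_fine = parts[0] if len(parts) == 1 else anp.concatenate(parts, axis=axis)
    return FineFeatures(f_csm=f_csm, f_akgm=f_akgm, f_fine=f_fine, stride=stride)


def fine_segment(ff: FineFeatures, params) -> np.ndarray:
    """Decode F_fine to a 2-channel per-pixel softmax at image resolution;
    channel 0 is the lesion probability."""
    from .coarse_seg import decode  # shared decoder pattern
    x, batched = _promote(ff.f_fine)
    out_hw = (np.shape(x)[2] * ff.stride, np.shape(x)[3] * ff.stride)
    logits = decode(params, x, out_hw)
    probs = softmax(logits, axis=1)
    return probs if batched else probs[0]
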
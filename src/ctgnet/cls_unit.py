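"""Lesion classification unit.

The lesion attention module (LAM) enhances the shared features with two
soft-masked copies of themselves before classification:

    F_ma  = F' ⊙ M_m      (gland attention)
    F_la  = F' ⊙ M_l      (lesion attention)
    F_LAM = F' + F_ma + F_la

where the single-channel soft masks are resized bilinearly to the feature
resolution and broadcast across channels. Global average pooling of F_LAM is
followed by an affine map to the global per-class feature matrix
G_global (D1 x C) and a second affine map to the C logits whose softmax is
H_score. The masks are NOT detached: classification gradients flow back into
the coarse-segmentation unit, which is the point of cross-task guidance.
"""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np

from ._autodiff import bilinear_resize, global_avg_pool, he_dense, softmax
from .backbone import SharedFeatures
from .coarse_seg import CH_GLAND, CH_LESION, CoarseMaskProbs


@dataclass
class LamFeatures:
    f_lam: np.ndarray
    f_ma: np.ndarray
    f_la: np.ndarray


@dataclass
class ClassPrediction:
    """g_global: (D1, C) or (B, D1, C); h_score on the simplex; raw logits."""

    g_global: np.ndarray
    h_score: np.ndarray
    logits: np.ndarray


def init_cls(d: int, d1: int, num_classes: int, rng: np.random.Generator,
             dtype=np.float32) -> dict:
    return {
        "fc_global": he_dense(rng, d1 * num_classes, d, dtype),
        "fc_score": he_dense(rng, num_classes, d1 * num_classes, dtype),
    }


def _mask_channel(m, channel):
    values = m.values if isinstance(m, CoarseMaskProbs) else m
    if np.ndim(values) == 4:
        return values[:, channel]
    return values[channel]


def lam(f: SharedFeatures, m, use_gland: bool = True,
        use_lesion: bool = True) -> LamFeatures:
    """Lesion attention: F_LAM = F' + F'⊙M_m + F'⊙M_l.

    ``m`` is a CoarseMaskProbs (or bare array) at any resolution; its gland
    and lesion channels are resized to the feature grid. The ``use_*`` flags
    zero the corresponding attention term for ablations.
    """
    fv = f.values
    batched = np.ndim(fv) == 4
    hw = (np.shape(fv)[-2], np.shape(fv)[-1])
    m_g = bilinear_resize(_mask_channel(m, CH_GLAND), hw)
    m_l = bilinear_resize(_mask_channel(m, CH_LESION), hw)
    if batched:
        m_g = anp.reshape(m_g, (np.shape(m_g)[0], 1) + hw)
        m_l = anp.reshape(m_l, (np.shape(m_l)[0], 1) + hw)
    f_ma = fv * m_g if use_gland else fv * 0.0
    f_la = fv * m_l if use_lesion else fv * 0.0
    return LamFeatures(f_lam=fv + f_ma + f_la, f_ma=f_ma, f_la=f_la)


def classify(lf: LamFeatures, params, num_classes: int) -> ClassPrediction:
    """GAP over F_LAM, affine map to G_global (D1 x C), affine map to logits,
    softmax to H_score."""
    x = lf.f_lam
    batched = np.ndim(x) == 4
    if not batched:
        x = anp.reshape(x, (1,) + np.shape(x))
    pooled = global_avg_pool(x)                                   # (B, D)
    d1 = params["fc_global"]["W"].shape[0] // num_classes
    g = anp.matmul(pooled, params["fc_global"]["W"].T) + params["fc_global"]["b"]
    g_global = anp.reshape(g, (-1, d1, num_classes))              # (B, D1, C)
    logits = anp.matmul(g, params["fc_score"]["W"].T) + params["fc_score"]["b"]
    h_score = softmax(logits, axis=1)
    if not batched:
        return ClassPrediction(g_global=g_global[0], h_score=h_score[0],
                               logits=logits[0])
    return ClassPrediction(g_global=g_global, h_score=h_score, logits=logits)
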
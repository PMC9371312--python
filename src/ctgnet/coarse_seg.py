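"""Coarse segmentation unit.

Decodes the shared features F' into the soft three-channel tissue mask
M = (M_l lesion, M_m gland, M_b background) at full image resolution, via
four x2 bilinear-upsampling stages each followed by two convolution layers,
then a 3-channel convolution, a bilinear resize to the exact image size, and
a per-pixel softmax. The soft mask (not a thresholded one) is what the other
units consume as attention.

Channel order is fixed throughout the package: 0 = lesion, 1 = gland,
2 = background.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import autograd.numpy as anp
import numpy as np

from ._autodiff import bilinear_resize, conv2d, group_norm, he_conv, relu, \
    softmax
from .backbone import SharedFeatures

CH_LESION, CH_GLAND, CH_BACKGROUND = 0, 1, 2


@dataclass
class CoarseMaskProbs:
    """Soft mask (3, H_img, W_img) or batched (B, 3, H_img, W_img);
    channels sum to 1 per pixel."""

    values: np.ndarray

    @property
    def batched(self) -> bool:
        return np.ndim(self.values) == 4


def _gn_groups(channels: int) -> int:
    g = min(8, channels)
    while channels % g:
        g -= 1
    return g


def init_decoder(in_channels: int, widths: Sequence[int], out_channels: int,
                 rng: np.random.Generator, dtype=np.float32) -> dict:
    """Shared constructor for the coarse and fine decoders: four upsampling
    stages of two 3x3 convolutions each (group-normalized), plus a 1x1
    output head."""
    stages = []
    c = in_channels
    for w in widths:
        convs = []
        for c_in in (c, w):
            layer = he_conv(rng, w, c_in, 3, dtype)
            layer["gamma"] = np.ones(w, dtype=dtype)
            layer["beta"] = np.zeros(w, dtype=dtype)
            convs.append(layer)
        stages.append(convs)
        c = w
    return {"stages": stages, "head": he_conv(rng, out_channels, c, 1, dtype)}


def decode(params, x, out_hw):
    """Four x2 upsample stages (two conv+GN+ReLU blocks each), 1x1 head conv,
    bilinear resize to out_hw."""
    for stage in params["stages"]:
        h, w = np.shape(x)[-2] * 2, np.shape(x)[-1] * 2
        x = bilinear_resize(x, (h, w))
        for layer in stage:
            x = conv2d(x, layer["W"], layer["b"])
            x = relu(group_norm(x, layer["gamma"], layer["beta"],
                                _gn_groups(layer["W"].shape[0])))
    x = conv2d(x, params["head"]["W"], params["head"]["b"])
    return bilinear_resize(x, out_hw)


def coarse_segment(f: SharedFeatures, params) -> CoarseMaskProbs:
    """Soft 3-channel mask at image resolution from shared features."""
    x = f.values
    batched = np.ndim(x) == 4
    if not batched:
        x = anp.reshape(x, (1,) + np.shape(x))
    out_hw = (np.shape(x)[2] * f.stride, np.shape(x)[3] * f.stride)
    logits = decode(params, x, out_hw)
    probs = softmax(logits, axis=1)
    if not batched:
        probs = probs[0]
    return CoarseMaskProbs(values=probs)


def hard_mask(m: CoarseMaskProbs) -> np.ndarray:
    """Per-pixel argmax label map; ties break toward the lower channel index
    (lesion < gland < background), which np.argmax guarantees."""
    values = np.asarray(m.values)
    axis = 1 if values.ndim == 4 else 0
    return np.argmax(values, axis=axis).astype(np.uint8)
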
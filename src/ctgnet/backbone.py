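"""Shared-feature backbone: convolutional encoder + atrous spatial pyramid
pooling (ASPP).

The encoder reduces the input image by the configured stride; ASPP then runs
one 1x1 branch plus one 3x3 dilated branch per dilation rate on the encoder
output, concatenates the branches along channels and projects back to D
channels with a 1x1 convolution. The multi-rate pyramid gives the shared
features a degree of scale robustness, which matters for small lesions.

The default encoder is a lightweight 4-stage stack sized for CPU-scale
experiments; a randomly initialized VGG16 feature stack (cut at stride 8) is
selectable for parity experiments. Pretrained weights are off by default and
must be supplied explicitly as an ``.npz`` path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple, Union

import autograd.numpy as anp
import numpy as np

from ._autodiff import avg_pool2, conv2d, he_conv, relu

# VGG16 convolutional widths up to the stride-8 cut (through conv4_3)
_VGG16_PLAN = [64, 64, "P", 128, 128, "P", 256, 256, 256, "P", 512, 512, 512]


@dataclass
class SharedFeatures:
    """Shared representation F' of shape (D, H, W) or batched (B, D, H, W)."""

    values: np.ndarray
    stride: int

    @property
    def batched(self) -> bool:
        return np.ndim(self.values) == 4


@dataclass
class BackboneConfig:
    kind: str = "lightweight"              # or "vgg16"
    channels: int = 64                     # D, depth of F'
    aspp_rates: Tuple[int, ...] = (1, 2, 4)
    stride: int = 8
    widths: Tuple[int, ...] = (8, 16, 32, 64)  # lightweight stage widths
    pretrained: Union[bool, str] = False

    def __post_init__(self):
        if not self.aspp_rates or any(r < 1 for r in self.aspp_rates):
            raise ValueError("aspp_rates must be non-empty with all rates >= 1")
        if self.stride < 1 or self.stride & (self.stride - 1):
            raise ValueError("stride must be a positive power of two")
        if self.kind not in ("lightweight", "vgg16"):
            raise ValueError(f"unknown encoder kind {self.kind!r}")
        if self.kind == "lightweight" and len(self.widths) != 4:
            raise ValueError("lightweight encoder expects 4 stage widths")

    @property
    def n_pools(self) -> int:
        return int(math.log2(self.stride))

    @property
    def encoder_channels(self) -> int:
        return self.widths[-1] if self.kind == "lightweight" else _VGG16_PLAN[-1]


def init_backbone(cfg: BackboneConfig, rng: np.random.Generator,
                  dtype=np.float32) -> dict:
    """Random (He) initialization of encoder + ASPP parameters."""
    params = {"enc": [], "aspp": {"branches": [], "proj": None}}
    if cfg.kind == "lightweight":
        c_in = 1
        for w in cfg.widths:
            params["enc"].append(he_conv(rng, w, c_in, 3, dtype))
            c_in = w
    else:
        if cfg.pretrained is True:
            raise ValueError(
                "pretrained=True requires a path to an .npz weights file; "
                "bundled ImageNet weights are not shipped")
        c_in = 1
        for item in _VGG16_PLAN:
            if item == "P":
                continue
            params["enc"].append(he_conv(rng, item, c_in, 3, dtype))
            c_in = item
        if isinstance(cfg.pretrained, str):
            loaded = np.load(cfg.pretrained)
            for i, layer in enumerate(params["enc"]):
                layer["W"] = loaded[f"conv{i}_W"].astype(dtype)
                layer["b"] = loaded[f"conv{i}_b"].astype(dtype)
    enc_ch = cfg.encoder_channels
    D = cfg.channels
    params["aspp"]["branches"].append(he_conv(rng, D, enc_ch, 1, dtype))
    for _ in cfg.aspp_rates:
        params["aspp"]["branches"].append(he_conv(rng, D, enc_ch, 3, dtype))
    params["aspp"]["proj"] = he_conv(rng, D, (1 + len(cfg.aspp_rates)) * D, 1, dtype)
    return params


def _encoder_forward(params, x, cfg: BackboneConfig):
    if cfg.kind == "lightweight":
        pools_after = set(range(cfg.n_pools))  # pool after the first n stages
        for i, layer in enumerate(params["enc"]):
            x = relu(conv2d(x, layer["W"], layer["b"]))
            if i in pools_after:
                x = avg_pool2(x)
        return x
    # vgg16: pools at the 'P' markers of the plan
    li = 0
    for item in _VGG16_PLAN:
        if item == "P":
            x = avg_pool2(x)
        else:
            layer = params["enc"][li]
            x = relu(conv2d(x, layer["W"], layer["b"]))
            li += 1
    return x


def _aspp_forward(params, x, cfg: BackboneConfig):
    branches = [relu(conv2d(x, params["aspp"]["branches"][0]["W"],
                            params["aspp"]["branches"][0]["b"]))]
    for rate, layer in zip(cfg.aspp_rates, params["aspp"]["branches"][1:]):
        branches.append(relu(conv2d(x, layer["W"], layer["b"], dilation=rate)))
    fused = anp.concatenate(branches, axis=1)
    proj = params["aspp"]["proj"]
    return relu(conv2d(fused, proj["W"], proj["b"]))


def extract_shared_features(image, cfg: BackboneConfig, params) -> SharedFeatures:
    """Compute F' for one image (H, W) or a batch (B, H, W) / (B, 1, H, W)."""
    x = anp.asarray(image) if isinstance(image, np.ndarray) else image
    batched = np.ndim(x) >= 3
    if np.ndim(x) == 2:
        x = anp.reshape(x, (1, 1) + np.shape(x))
    elif np.ndim(x) == 3:
        x = anp.reshape(x, (np.shape(x)[0], 1) + np.shape(x)[1:])
    H_img, W_img = np.shape(x)[2], np.shape(x)[3]
    if H_img < cfg.stride or W_img < cfg.stride:
        raise ValueError(
            f"image {H_img}x{W_img} smaller than backbone stride {cfg.stride}")
    feats = _aspp_forward(params, _encoder_forward(params, x, cfg), cfg)
    if not batched:
        feats = feats[0]
    return SharedFeatures(values=feats, stride=cfg.stride)
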
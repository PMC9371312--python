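"""Full network assembly: configuration, parameter initialization, the joint
forward pass, and checkpoint I/O.

The forward pass follows the cross-task wiring: shared features from the
backbone feed the coarse segmentation unit; its soft mask guides the lesion
attention of the classification unit; the class prediction and the gland mask
guide the CSM/AKGM branches of the fine segmentation unit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from . import cls_unit, coarse_seg, fine_seg
from .backbone import BackboneConfig, SharedFeatures, extract_shared_features, init_backbone
from .coarse_seg import CH_GLAND, CoarseMaskProbs, init_decoder
from .cls_unit import ClassPrediction, LamFeatures, init_cls


@dataclass
class ClsConfig:
    d1: int = 32
    num_classes: int = 2
    use_lam: bool = True          # False: plain GAP classifier on F'
    lam_use_gland: bool = True    # F_ma term
    lam_use_lesion: bool = True   # F_la term


@dataclass
class FineConfig:
    use_csm: bool = True
    use_akgm: bool = True
    qk_channels: Optional[int] = None  # default max(1, D // 8)


@dataclass
class ModelConfig:
    image_size: int = 256
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    cls: ClsConfig = field(default_factory=ClsConfig)
    fine: FineConfig = field(default_factory=FineConfig)
    decoder_widths: Optional[Tuple[int, ...]] = None  # default derived from D

    def __post_init__(self):
        if self.backbone.channels < self.cls.num_classes:
            raise ValueError("feature depth D must be >= number of classes")
        if not (self.fine.use_csm or self.fine.use_akgm):
            raise ValueError("at least one of CSM/AKGM must be enabled")

    @property
    def widths(self) -> Tuple[int, ...]:
        if self.decoder_widths is not None:
            return tuple(self.decoder_widths)
        d = self.backbone.channels
        return (max(d // 2, 8), max(d // 4, 8), max(d // 8, 8), max(d // 8, 8))

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ModelOutput:
    shared: SharedFeatures
    coarse: CoarseMaskProbs
    lam: LamFeatures
    cls_pred: ClassPrediction
    fine_probs: np.ndarray  # (B, 2, H_img, W_img), channel 0 = lesion


def init_params(cfg: ModelConfig, rng: np.random.Generator,
                dtype=np.float32) -> dict:
    D = cfg.backbone.channels
    d1 = cfg.cls.d1
    C = cfg.cls.num_classes
    fine_in = (d1 if cfg.fine.use_csm else 0) + (D if cfg.fine.use_akgm else 0)
    params = {
        "backbone": init_backbone(cfg.backbone, rng, dtype),
        "coarse": init_decoder(D, cfg.widths, 3, rng, dtype),
        "cls": init_cls(D, d1, C, rng, dtype),
        "fine": {"decoder": init_decoder(fine_in, cfg.widths, 2, rng, dtype)},
    }
    if cfg.fine.use_csm:
        params["fine"]["csm"] = fine_seg.init_csm(D, d1, C, rng, dtype)
    if cfg.fine.use_akgm:
        params["fine"]["akgm"] = fine_seg.init_akgm(
            D, rng, cfg.fine.qk_channels, dtype)
    return params


def forward(params, images, cfg: ModelConfig) -> ModelOutput:
    """Joint forward pass on a batch (B, H, W) or (B, 1, H, W) in [0, 1]."""
    shared = extract_shared_features(images, cfg.backbone, params["backbone"])
    coarse = coarse_seg.coarse_segment(shared, params["coarse"])
    if cfg.cls.use_lam:
        lam_feats = cls_unit.lam(shared, coarse,
                                 use_gland=cfg.cls.lam_use_gland,
                                 use_lesion=cfg.cls.lam_use_lesion)
    else:
        zero = shared.values * 0.0
        lam_feats = LamFeatures(f_lam=shared.values, f_ma=zero, f_la=zero)
    pred = cls_unit.classify(lam_feats, params["cls"], cfg.cls.num_classes)
    f_csm = (fine_seg.csm(shared, pred, params["fine"]["csm"])
             if cfg.fine.use_csm else None)
    if cfg.fine.use_akgm:
        m_vals = coarse.values
        m_gland = m_vals[:, CH_GLAND] if np.ndim(m_vals) == 4 else m_vals[CH_GLAND]
        f_akgm = fine_seg.akgm(shared, m_gland, params["fine"]["akgm"])
    else:
        f_akgm = None
    ff = fine_seg.fuse(f_csm, f_akgm, shared.stride)
    fine_probs = fine_seg.fine_segment(ff, params["fine"]["decoder"])
    return ModelOutput(shared=shared, coarse=coarse, lam=lam_feats,
                       cls_pred=pred, fine_probs=fine_probs)


# -- checkpoint I/O ---------------------------------------------------------

def _flatten_tree(tree, prefix=""):
    items = {}
    if isinstance(tree, dict):
        for key, val in tree.items():
            items.update(_flatten_tree(val, f"{prefix}{key}/"))
    elif isinstance(tree, (list, tuple)):
        for i, val in enumerate(tree):
            items.update(_flatten_tree(val, f"{prefix}{i}/"))
    else:
        items[prefix.rstrip("/")] = np.asarray(tree)
    return items


def _set_in_tree(tree, keys, value):
    key = keys[0]
    if isinstance(tree, list):
        key = int(key)
    if len(keys) == 1:
        tree[key] = value
    else:
        _set_in_tree(tree[key], keys[1:], value)


def save_checkpoint(path, params, cfg: ModelConfig) -> None:
    """Serialize parameters + config (with its hash) to an .npz file."""
    flat = _flatten_tree(params)
    meta = json.dumps({"config": cfg.to_dict(), "hash": cfg.hash()}, default=str)
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **flat)


def load_checkpoint(path, cfg: Optional[ModelConfig] = None):
    """Load (params, cfg) from an .npz checkpoint.

    If ``cfg`` is given, its hash must match the embedded one; a mismatch is
    reported with both signatures.
    """
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if cfg is not None and cfg.hash() != meta["hash"]:
            raise ValueError(
                f"checkpoint/config mismatch: checkpoint {meta['hash']} vs "
                f"requested {cfg.hash()}")
        saved_cfg = config_from_dict(meta["config"])
        template = init_params(saved_cfg, np.random.default_rng(0))
        for key in data.files:
            if key == "__meta__":
                continue
            value = data[key]
            _set_in_tree(template, key.split("/"), value if value.ndim else
                         value.astype(value.dtype))
    return template, saved_cfg


def config_from_dict(d: dict) -> ModelConfig:
    """Build a ModelConfig from a (possibly partial) nested plain dict."""
    d = dict(d)
    bb = dict(d.get("backbone", {}))
    if "aspp_rates" in bb:
        bb["aspp_rates"] = tuple(bb["aspp_rates"])
    if "widths" in bb:
        bb["widths"] = tuple(bb["widths"])
    cls = dict(d.get("cls", {}))
    fine = dict(d.get("fine", {}))
    dw = d.get("decoder_widths")
    return ModelConfig(
        image_size=int(d.get("image_size", 256)),
        backbone=BackboneConfig(**bb),
        cls=ClsConfig(**cls),
        fine=FineConfig(**fine),
        decoder_widths=tuple(dw) if dw is not None else None,
    )
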
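"""Evaluation metrics for lesion segmentation and image classification.

Segmentation metrics compare the predicted lesion pixel set A_p with the
ground-truth set A_g:

    DSC  = 2|A_g ∩ A_p| / (|A_g| + |A_p|)
    JI   = |A_g ∩ A_p| / |A_g ∪ A_p|
    TPR  = |A_g ∩ A_p| / |A_g|
    FPR  = |(A_g ∪ A_p) \\ A_g| / |A_g ∪ A_p|
    tFPR = |(A_g ∪ A_p) \\ A_g| / |A_g|   (can exceed 1 for small lesions)

Empty-mask conventions (for normal images): if both sets are empty,
dsc = ji = tpr = 1 and fpr = tfpr = 0; if A_g is empty but A_p is not,
dsc = ji = tpr = 0, fpr = 1 and tFPR is undefined (NaN) and excluded from
aggregation with a logged count.

Classification metrics come from the confusion counts at a score threshold
(default 0.5) plus the rank-based (Mann-Whitney, midrank ties) AUC.
Segmentation metrics are averaged per image; classification metrics are
computed once over the pooled predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

METRIC_COLUMNS = ["dsc", "ji", "tpr", "fpr", "tfpr",
                  "auc", "acc", "sen", "spc", "pre", "f1"]


@dataclass
class SegMetrics:
    dsc: float
    ji: float
    tpr: float
    fpr: float
    tfpr: float


@dataclass
class ClsMetrics:
    auc: float
    acc: float
    sen: float
    spc: float
    pre: float
    f1: float
    tp: int
    tn: int
    fp: int
    fn: int


def seg_metrics(pred_mask: np.ndarray, true_mask: np.ndarray) -> SegMetrics:
    """Per-image segmentation metrics over binary masks of equal shape."""
    pred_mask = np.asarray(pred_mask)
    true_mask = np.asarray(true_mask)
    if pred_mask.shape != true_mask.shape:
        raise ValueError(
            f"shape mismatch: pred {pred_mask.shape} vs true {true_mask.shape}")
    ap = pred_mask.astype(bool)
    ag = true_mask.astype(bool)
    n_g = int(ag.sum())
    n_p = int(ap.sum())
    inter = int((ag & ap).sum())
    union = int((ag | ap).sum())
    false_pos = union - n_g  # |(A_g ∪ A_p) \ A_g|

    if n_g == 0 and n_p == 0:
        return SegMetrics(dsc=1.0, ji=1.0, tpr=1.0, fpr=0.0, tfpr=0.0)
    if n_g == 0:
        return SegMetrics(dsc=0.0, ji=0.0, tpr=0.0, fpr=1.0, tfpr=float("nan"))
    return SegMetrics(
        dsc=2.0 * inter / (n_g + n_p),
        ji=inter / union,
        tpr=inter / n_g,
        fpr=false_pos / union,
        tfpr=false_pos / n_g,
    )


def cls_metrics(scores: Sequence[float], labels: Sequence[int],
                threshold: float = 0.5) -> ClsMetrics:
    """Binary classification metrics from positive-class scores.

    If the labels are degenerate (only one class present) the AUC is
    undefined and reported as NaN with a warning; threshold metrics are
    still returned.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    pred = scores >= threshold
    pos = labels == 1
    tp = int(np.sum(pred & pos))
    tn = int(np.sum(~pred & ~pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))
    total = tp + tn + fp + fn
    acc = (tp + tn) / total if total else float("nan")
    sen = tp / (tp + fn) if (tp + fn) else float("nan")
    spc = tn / (tn + fp) if (tn + fp) else float("nan")
    pre = tp / (tp + fp) if (tp + fp) else float("nan")
    f1 = (2 * pre * sen / (pre + sen)
          if np.isfinite(pre) and np.isfinite(sen) and (pre + sen) > 0
          else (0.0 if tp == 0 and (fp or fn) else float("nan")))
    if len(np.unique(labels)) < 2:
        warnings.warn("degenerate label set: AUC undefined, reported as NaN")
        auc = float("nan")
    else:
        auc = float(roc_auc_score(labels, scores))
    return ClsMetrics(auc=auc, acc=acc, sen=sen, spc=spc, pre=pre, f1=f1,
                      tp=tp, tn=tn, fp=fp, fn=fn)


def aggregate(per_image: List[SegMetrics]) -> dict:
    """Unweighted mean of per-image segmentation metrics.

    Images whose tFPR is undefined (empty ground truth with false positives)
    are excluded from the tFPR mean; their count is reported under
    ``tfpr_excluded``.
    """
    if not per_image:
        raise ValueError("cannot aggregate an empty metric list")
    out = {}
    for name in ["dsc", "ji", "tpr", "fpr"]:
        out[name] = float(np.mean([getattr(m, name) for m in per_image]))
    tfpr = np.array([m.tfpr for m in per_image], dtype=float)
    defined = np.isfinite(tfpr)
    out["tfpr"] = float(tfpr[defined].mean()) if defined.any() else float("nan")
    out["tfpr_excluded"] = int((~defined).sum())
    return out


def summarize(seg_list: List[SegMetrics], scores: Sequence[float],
              labels: Sequence[int], threshold: float = 0.5) -> pd.DataFrame:
    """One-row summary table with the 11 standard metric columns."""
    seg = aggregate(seg_list)
    cls = cls_metrics(scores, labels, threshold=threshold)
    row = {name: seg[name] for name in ["dsc", "ji", "tpr", "fpr", "tfpr"]}
    row.update({name: getattr(cls, name)
                for name in ["auc", "acc", "sen", "spc", "pre", "f1"]})
    return pd.DataFrame([row], columns=METRIC_COLUMNS)
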
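"""Joint objective: Dice segmentation losses, classification cross-entropy,
and dynamic weight averaging (DWA) between the two tasks.

The network is trained end-to-end with

    L_total = lambda_1 * L_cls + lambda_2 * (L_cseg + L_fseg),

where the coarse- and fine-segmentation Dice losses share one task weight.
DWA assigns (lambda_1, lambda_2) each epoch from the relative descent rate of
the per-task epoch-mean losses, w_k = L_k(t-1) / L_k(t-2), through a softmax
at temperature T (default 2) scaled by the number of tasks K = 2, so the
weights always sum to K. For the first two epochs both weights are 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import autograd.numpy as anp
import numpy as np

DICE_EPS = 1.0  # smoothing in numerator and denominator; empty-vs-empty -> Dice 1


@dataclass
class TaskWeightState:
    """DWA bookkeeping: per-task epoch-mean loss history and current weights."""

    loss_history: Dict[str, List[float]] = field(
        default_factory=lambda: {"cls": [], "seg": []})
    weights: Tuple[float, float] = (1.0, 1.0)
    temperature: float = 2.0
    num_tasks: int = 2

    def record(self, l_cls: float, l_seg: float) -> None:
        self.loss_history["cls"].append(float(l_cls))
        self.loss_history["seg"].append(float(l_seg))


@dataclass
class LossBundle:
    l_cls: float
    l_cseg: float
    l_fseg: float
    l_total: float


def dice_loss(pred, target, eps: float = DICE_EPS):
    """Soft multi-class Dice loss, 1 - mean over classes of per-class Dice.

    pred: per-class probability maps (C, H, W) or (B, C, H, W), per-pixel
    normalized; target: one-hot of the same shape. Per-class Dice is
    (2 * sum(p*t) + eps) / (sum(p) + sum(t) + eps), computed per sample and
    averaged over classes and batch. Differentiable in ``pred``.
    """
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs target {target.shape}")
    batched = pred.ndim == 4
    if not batched:
        pred = anp.reshape(pred, (1,) + pred.shape)
        target = np.reshape(target, (1,) + target.shape)
    B, C = pred.shape[0], pred.shape[1]
    p = anp.reshape(pred, (B, C, -1))
    t = np.reshape(target, (B, C, -1))
    inter = anp.sum(p * t, axis=2)
    dice = (2.0 * inter + eps) / (anp.sum(p, axis=2) + np.sum(t, axis=2) + eps)
    return 1.0 - anp.mean(dice)


def cls_loss(pred, labels):
    """Mean cross-entropy -log h_score[label].

    ``pred`` is a ClassPrediction (its logits are used through a log-softmax
    for numerical stability) or a bare score array of shape (C,) or (B, C) on
    the probability simplex.
    """
    labels = np.atleast_1d(np.asarray(labels, dtype=int))
    logits = getattr(pred, "logits", None)
    if logits is not None:
        z = anp.atleast_2d(logits)
        C = z.shape[1]
        if np.any((labels < 0) | (labels >= C)):
            raise ValueError(f"labels {labels} out of range [0, {C})")
        z = z - anp.max(z, axis=1, keepdims=True)
        logp = z - anp.log(anp.sum(anp.exp(z), axis=1, keepdims=True))
        onehot = np.eye(C)[labels]
        return -anp.mean(anp.sum(logp * onehot, axis=1))
    scores = anp.atleast_2d(pred)
    C = scores.shape[1]
    if np.any((labels < 0) | (labels >= C)):
        raise ValueError(f"labels {labels} out of range [0, {C})")
    picked = scores[np.arange(len(labels)), labels]
    return -anp.mean(anp.log(picked))


def dwa_update(state: TaskWeightState, epoch: int) -> TaskWeightState:
    """Return ``state`` with weights for 1-based ``epoch`` set by DWA.

    Requires ``state.loss_history`` to contain the epoch-mean losses of all
    completed epochs (epochs 1..epoch-1).
    """
    K = state.num_tasks
    T = state.temperature
    if epoch <= 2:
        state.weights = tuple(1.0 for _ in range(K))
        return state
    hist = [state.loss_history["cls"], state.loss_history["seg"]]
    if any(len(h) < epoch - 1 for h in hist):
        raise ValueError(
            f"loss history too short for epoch {epoch}: "
            f"{[len(h) for h in hist]} entries")
    prev = [h[epoch - 2] for h in hist]   # L_k(t-1)
    prev2 = [h[epoch - 3] for h in hist]  # L_k(t-2)
    if any(p <= 0 for p in prev) or any(p <= 0 for p in prev2):
        raise ValueError("nonpositive historical loss in DWA update")
    w = np.array([a / b for a, b in zip(prev, prev2)])
    e = np.exp(w / T)
    state.weights = tuple(float(x) for x in K * e / e.sum())
    return state


def total_loss(l_cls, l_cseg, l_fseg, weights: TaskWeightState) -> LossBundle:
    """Joint objective; returns all four scalars for logging."""
    lam1, lam2 = weights.weights
    total = lam1 * l_cls + lam2 * (l_cseg + l_fseg)
    return LossBundle(l_cls=l_cls, l_cseg=l_cseg, l_fseg=l_fseg, l_total=total)
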
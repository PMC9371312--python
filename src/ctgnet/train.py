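"""End-to-end training, prediction and experiment orchestration.

The training loop optimizes the joint loss
L_total = lambda_1 * L_cls + lambda_2 * (L_cseg + L_fseg) with Adam
(lr 1e-4, beta1 0.9, beta2 0.99, eps 1e-8 by default), updates the task
weights by dynamic weight averaging once per epoch from the epoch-mean task
losses, and stops early when the validation total loss has not improved for
``patience`` consecutive epochs, keeping the best-validation parameters.

The desk profile shrinks the problem to CPU scale (64x64 phantoms, a narrow
backbone, 20 epochs, batch 8, lr 3e-3); the full profile keeps the reference
hyperparameters (256x256, batch 16, lr 1e-4, 100 epochs).
"""

from __future__ import annotations

import copy
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from ._autodiff import Adam, value_and_grad
from . import metrics as metrics_mod
from .coarse_seg import hard_mask
from .losses import TaskWeightState, cls_loss, dice_loss, dwa_update, total_loss
from .model import ModelConfig, config_from_dict, forward, init_params, \
    load_checkpoint, save_checkpoint
from .phantom import PhantomConfig, PhantomSample, generate_dataset, read_dataset


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    adam_beta1: float = 0.9
    adam_beta2: float = 0.99
    adam_eps: float = 1e-8
    max_epochs: int = 100
    batch_size: int = 16
    patience: int = 10
    seed: int = 0
    device: str = "cpu"
    desk_profile: bool = False

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.patience > self.max_epochs:
            raise ValueError("patience must be <= max_epochs")
        if self.device != "cpu":
            raise ValueError("only cpu execution is supported")


# desk-profile defaults, overlaid by explicit config values
DESK_MODEL = {
    "image_size": 64,
    "backbone": {"kind": "lightweight", "channels": 32,
                 "widths": [8, 16, 24, 32], "aspp_rates": [1, 2, 4], "stride": 8},
    "cls": {"d1": 16, "num_classes": 2},
    "fine": {"use_csm": True, "use_akgm": True},
    "decoder_widths": [16, 8, 8, 4],
}
DESK_TRAIN = {"learning_rate": 3e-3, "max_epochs": 20, "batch_size": 8,
              "desk_profile": True}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in (override or {}).items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = val
    return out


@dataclass
class ExperimentConfig:
    phantom: PhantomConfig
    model: ModelConfig
    train: TrainConfig
    n_train: int = 200
    n_val: int = 50
    n_test: int = 50
    threshold: float = 0.5
    raw: dict = field(default_factory=dict)


def load_experiment_config(source) -> ExperimentConfig:
    """Build an ExperimentConfig from a YAML path or a nested dict.

    When ``train.desk_profile`` is true, the desk defaults seed the model and
    train sections and explicit values overlay them.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = copy.deepcopy(source or {})
    model_d = raw.get("model", {}) or {}
    train_d = raw.get("train", {}) or {}
    if train_d.get("desk_profile"):
        model_d = _deep_merge(DESK_MODEL, model_d)
        train_d = _deep_merge(DESK_TRAIN, train_d)
    phantom_d = dict(raw.get("phantom", {}) or {})
    n_train = int(phantom_d.pop("n_train", 200))
    n_val = int(phantom_d.pop("n_val", 50))
    n_test = int(phantom_d.pop("n_test", 50))
    if "lesion_radius_range" in phantom_d:
        phantom_d["lesion_radius_range"] = tuple(phantom_d["lesion_radius_range"])
    eval_d = raw.get("eval", {}) or {}
    return ExperimentConfig(
        phantom=PhantomConfig(**phantom_d),
        model=config_from_dict(model_d),
        train=TrainConfig(**train_d),
        n_train=n_train, n_val=n_val, n_test=n_test,
        threshold=float(eval_d.get("threshold", 0.5)),
        raw=raw,
    )


# -- dataset tensors --------------------------------------------------------

def samples_to_arrays(samples: Sequence[PhantomSample], image_size: int,
                      num_classes: int = 2,
                      dtype=np.float32) -> Dict[str, np.ndarray]:
    """Stack samples into network-ready arrays, resizing if needed.

    With ``num_classes == 2`` the 3-class phantom labels collapse to
    normal-vs-lesion; otherwise they are kept as is.
    """
    from skimage.transform import resize

    imgs, coarse, fine, labels = [], [], [], []
    for s in samples:
        img = s.image
        cmask = s.coarse_mask
        lmask = s.lesion_mask
        if img.shape != (image_size, image_size):
            img = resize(img, (image_size, image_size), order=1,
                         anti_aliasing=False)
            cmask = resize(cmask, (image_size, image_size), order=0,
                           preserve_range=True).astype(np.uint8)
            lmask = resize(lmask, (image_size, image_size), order=0,
                           preserve_range=True).astype(np.uint8)
        imgs.append(img)
        # channel order (lesion, gland, background)
        coarse.append(np.stack([cmask == 2, cmask == 1, cmask == 0]))
        fine.append(np.stack([lmask == 1, lmask == 0]))
        labels.append(min(s.class_label, 1) if num_classes == 2
                      else s.class_label)
    return {
        "images": np.asarray(imgs, dtype=dtype)[:, None],
        "coarse": np.asarray(coarse, dtype=dtype),
        "fine": np.asarray(fine, dtype=dtype),
        "labels": np.asarray(labels, dtype=int),
        "raw_labels": np.asarray([s.class_label for s in samples], dtype=int),
    }


def _unbox(x) -> float:
    while hasattr(x, "_value"):
        x = x._value
    return float(x)


def batch_losses(params, cfg: ModelConfig, images, coarse_t, fine_t, labels,
                 weights: TaskWeightState):
    """Joint loss of one batch; returns (total, components dict of floats)."""
    out = forward(params, images, cfg)
    l_cls = cls_loss(out.cls_pred, labels)
    l_cseg = dice_loss(out.coarse.values, coarse_t)
    l_fseg = dice_loss(out.fine_probs, fine_t)
    bundle = total_loss(l_cls, l_cseg, l_fseg, weights)
    comps = {"l_cls": _unbox(l_cls), "l_cseg": _unbox(l_cseg),
             "l_fseg": _unbox(l_fseg)}
    return bundle.l_total, comps


@dataclass
class TrainResult:
    params: dict                 # best-validation parameters
    log: pd.DataFrame
    best_epoch: int
    best_val_loss: float
    stopped_early: bool


def _eval_pass(params, cfg: ModelConfig, data, weights, threshold=0.5,
               chunk=16):
    """Validation losses and quick metrics in evaluation mode."""
    n = len(data["images"])
    comps_sum = np.zeros(3)
    dscs, preds, scores = [], [], []
    for lo in range(0, n, chunk):
        sl = slice(lo, min(lo + chunk, n))
        out = forward(params, data["images"][sl], cfg)
        l_cls = _unbox(cls_loss(out.cls_pred, data["labels"][sl]))
        l_cseg = _unbox(dice_loss(out.coarse.values, data["coarse"][sl]))
        l_fseg = _unbox(dice_loss(out.fine_probs, data["fine"][sl]))
        comps_sum += np.array([l_cls, l_cseg, l_fseg]) * (sl.stop - sl.start)
        fine_hard = np.asarray(out.fine_probs)[:, 0] >= threshold
        for i in range(sl.stop - sl.start):
            dscs.append(metrics_mod.seg_metrics(
                fine_hard[i], data["fine"][sl][i, 0] > 0.5).dsc)
        h = np.asarray(out.cls_pred.h_score)
        scores.extend(h[:, 1].tolist())
        preds.extend(np.argmax(h, axis=1).tolist())
    comps = comps_sum / n
    lam1, lam2 = weights.weights
    val_total = lam1 * comps[0] + lam2 * (comps[1] + comps[2])
    acc = float(np.mean(np.asarray(preds) == data["labels"]))
    return {"val_loss": float(val_total), "val_l_cls": comps[0],
            "val_l_cseg": comps[1], "val_l_fseg": comps[2],
            "val_dsc": float(np.mean(dscs)), "val_acc": acc}


def train(model_cfg: ModelConfig, train_cfg: TrainConfig,
          train_samples: Sequence[PhantomSample],
          val_samples: Sequence[PhantomSample],
          log_path=None, checkpoint_path=None,
          fixed_weights: Optional[Tuple[float, float]] = None) -> TrainResult:
    """Run the full training loop on phantom samples.

    ``fixed_weights`` freezes (lambda_1, lambda_2) instead of DWA (used for
    controlled experiments). All randomness (init, shuffling) derives from
    ``train_cfg.seed``.
    """
    rng = np.random.default_rng(train_cfg.seed)
    params = init_params(model_cfg, rng)
    data = samples_to_arrays(train_samples, model_cfg.image_size,
                             model_cfg.cls.num_classes)
    val = samples_to_arrays(val_samples, model_cfg.image_size,
                            model_cfg.cls.num_classes)
    n = len(data["images"])
    if n == 0:
        raise ValueError("empty training dataset")

    adam = Adam(params, lr=train_cfg.learning_rate, beta1=train_cfg.adam_beta1,
                beta2=train_cfg.adam_beta2, eps=train_cfg.adam_eps)
    state = TaskWeightState()
    rows: List[dict] = []
    best_val = np.inf
    best_params = params
    best_epoch = 0
    bad_epochs = 0
    stopped = False

    for epoch in range(1, train_cfg.max_epochs + 1):
        if fixed_weights is not None:
            state.weights = fixed_weights
        else:
            state = dwa_update(state, epoch)
        order = rng.permutation(n)
        comp_sums = np.zeros(3)
        n_batches = 0
        for lo in range(0, n, train_cfg.batch_size):
            idx = order[lo:lo + train_cfg.batch_size]
            comps_cell = {}

            def objective(p):
                total, comps = batch_losses(
                    p, model_cfg, data["images"][idx], data["coarse"][idx],
                    data["fine"][idx], data["labels"][idx], state)
                comps_cell.update(comps)
                return total

            loss_val, grads = value_and_grad(objective)(params)
            if not np.isfinite(loss_val):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches}")
            params = adam.step(params, grads)
            comp_sums += np.array([comps_cell["l_cls"], comps_cell["l_cseg"],
                                   comps_cell["l_fseg"]])
            n_batches += 1
        epoch_means = comp_sums / n_batches
        state.record(epoch_means[0], epoch_means[1] + epoch_means[2])

        val_stats = _eval_pass(params, model_cfg, val, state)
        lam1, lam2 = state.weights
        rows.append({"epoch": epoch, "l_cls": epoch_means[0],
                     "l_cseg": epoch_means[1], "l_fseg": epoch_means[2],
                     "lambda1": lam1, "lambda2": lam2,
                     "l_total": lam1 * epoch_means[0]
                     + lam2 * (epoch_means[1] + epoch_means[2]),
                     **val_stats})
        if val_stats["val_loss"] < best_val:
            best_val = val_stats["val_loss"]
            best_params = copy.deepcopy(params)
            best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= train_cfg.patience:
                stopped = True
                break

    log = pd.DataFrame(rows)
    if log_path is not None:
        log.to_csv(log_path, index=False)
    if checkpoint_path is not None:
        save_checkpoint(checkpoint_path, best_params, model_cfg)
    return TrainResult(params=best_params, log=log, best_epoch=best_epoch,
                       best_val_loss=float(best_val), stopped_early=stopped)


def overfit_single_batch(model_cfg: ModelConfig,
                         samples: Sequence[PhantomSample], steps: int = 300,
                         lr: float = 3e-3, seed: int = 0) -> dict:
    """Fit one fixed batch with lambda = (1, 1); capacity sanity check.

    Returns the loss components of the final step.
    """
    rng = np.random.default_rng(seed)
    params = init_params(model_cfg, rng)
    data = samples_to_arrays(samples, model_cfg.image_size,
                             model_cfg.cls.num_classes)
    weights = TaskWeightState(weights=(1.0, 1.0))
    adam = Adam(params, lr=lr)
    comps_cell = {}

    def objective(p):
        total, comps = batch_losses(p, model_cfg, data["images"],
                                    data["coarse"], data["fine"],
                                    data["labels"], weights)
        comps_cell.update(comps)
        return total

    for _ in range(steps):
        _, grads = value_and_grad(objective)(params)
        params = adam.step(params, grads)
    # final forward to report post-update losses
    _, comps = batch_losses(params, model_cfg, data["images"], data["coarse"],
                            data["fine"], data["labels"], weights)
    comps["params"] = params
    return comps


# -- inference and evaluation ----------------------------------------------

def predict(params_or_checkpoint, samples, out_dir, cfg: ModelConfig = None,
            threshold: float = 0.5, chunk: int = 16,
            save_probs: bool = False) -> Path:
    """Write fine/coarse mask PNGs and a per-image class-score CSV.

    ``samples`` is a list of PhantomSample or a manifest path. Returns the
    path of scores.csv. With ``save_probs`` the soft coarse and fine
    probability maps are also stored per image in a compressed ``.npz``.
    Deterministic in evaluation mode.
    """
    if isinstance(params_or_checkpoint, (str, Path)):
        params, cfg = load_checkpoint(params_or_checkpoint, cfg)
    else:
        params = params_or_checkpoint
        if cfg is None:
            raise ValueError("cfg is required when passing raw parameters")
    if isinstance(samples, (str, Path)):
        samples = read_dataset(samples)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    data = samples_to_arrays(samples, cfg.image_size, cfg.cls.num_classes)
    rows = []
    for lo in range(0, len(samples), chunk):
        sl = slice(lo, min(lo + chunk, len(samples)))
        out = forward(params, data["images"][sl], cfg)
        fine = np.asarray(out.fine_probs)
        coarse_labels = hard_mask(out.coarse)
        h = np.asarray(out.cls_pred.h_score)
        for j, i in enumerate(range(sl.start, sl.stop)):
            stem = f"sample_{i:05d}"
            iio.imwrite(out_dir / f"{stem}_fine.png",
                        ((fine[j, 0] >= threshold) * 255).astype(np.uint8))
            iio.imwrite(out_dir / f"{stem}_coarse.png",
                        coarse_labels[j].astype(np.uint8))
            if save_probs:
                np.savez_compressed(
                    out_dir / f"{stem}_probs.npz",
                    coarse=np.asarray(out.coarse.values)[j], fine=fine[j])
            row = {"filename": f"{stem}.png",
                   "predicted_class": int(np.argmax(h[j]))}
            for c in range(h.shape[1]):
                row[f"score_{c}"] = float(h[j, c])
            rows.append(row)
    scores_path = out_dir / "scores.csv"
    pd.DataFrame(rows).to_csv(scores_path, index=False)
    return scores_path


def evaluate_predictions(pred_dir, truth_samples, threshold: float = 0.5
                         ) -> pd.DataFrame:
    """Compare predicted masks/scores in ``pred_dir`` against ground truth."""
    pred_dir = Path(pred_dir)
    if isinstance(truth_samples, (str, Path)):
        truth_samples = read_dataset(truth_samples)
    scores_df = pd.read_csv(pred_dir / "scores.csv")
    seg_list, scores, labels = [], [], []
    for i, s in enumerate(truth_samples):
        stem = f"sample_{i:05d}"
        pred_mask = np.asarray(iio.imread(pred_dir / f"{stem}_fine.png")) > 0
        seg_list.append(metrics_mod.seg_metrics(pred_mask, s.lesion_mask > 0))
        scores.append(float(scores_df.iloc[i]["score_1"]))
        labels.append(min(s.class_label, 1))
    return metrics_mod.summarize(seg_list, scores, labels, threshold=threshold)


def run_experiment(config, out_dir, seed: Optional[int] = None) -> pd.DataFrame:
    """Generate phantoms, train, predict on the held-out test set, evaluate.

    Writes a self-describing results directory: config.yaml, run.json (run id,
    sizes, timing), train_log.csv, checkpoint.npz, test dataset, predictions
    and metrics.csv. Returns the metrics table.
    """
    exp = load_experiment_config(config)
    if seed is not None:
        exp.train.seed = int(seed)
        exp.phantom.seed = int(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    t0 = time.time()
    train_s = generate_dataset(exp.phantom, exp.n_train, start_index=0)
    val_s = generate_dataset(exp.phantom, exp.n_val, start_index=exp.n_train)
    test_s = generate_dataset(exp.phantom, exp.n_test,
                              start_index=exp.n_train + exp.n_val)
    from .phantom import write_dataset
    write_dataset(test_s, out_dir / "test_data")

    result = train(exp.model, exp.train, train_s, val_s,
                   log_path=out_dir / "train_log.csv",
                   checkpoint_path=out_dir / "checkpoint.npz")
    predict(result.params, test_s, out_dir / "predictions", cfg=exp.model,
            threshold=exp.threshold)
    metrics_df = evaluate_predictions(out_dir / "predictions", test_s,
                                      threshold=exp.threshold)
    metrics_df.to_csv(out_dir / "metrics.csv", index=False)

    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump({"phantom": {**{k: v for k, v in asdict(exp.phantom).items()},
                                    "n_train": exp.n_train, "n_val": exp.n_val,
                                    "n_test": exp.n_test},
                        "model": exp.model.to_dict(),
                        "train": asdict(exp.train),
                        "eval": {"threshold": exp.threshold}},
                       fh, default_flow_style=None)
    run_meta = {"run_id": exp.model.hash(), "seed": exp.train.seed,
                "best_epoch": result.best_epoch,
                "best_val_loss": result.best_val_loss,
                "stopped_early": result.stopped_early,
                "wall_time_s": round(time.time() - t0, 2)}
    with open(out_dir / "run.json", "w") as fh:
        json.dump(run_meta, fh, indent=2)
    return metrics_df
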
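"""Augmentation, metrics, dataset splitting, and the desk-scale training loop.

Augmentations mirror what field scanning perturbs: a rigid translation of the
whole plant (positioning error), isotropic rescaling about the centroid
(plants from 15 cm seedlings to 1.2 m canopies), and a mirror flip through
the XZ plane (one-sided scanning). None of them touches labels or point
order.

Metrics are the two-class organ-segmentation standards: per-class
one-vs-rest accuracy ``(TP+TN)/N`` and IoU ``TP/(TP+FP+FN)``, with mIoU and
mAcc their means over the leaf and stem classes, all reported as
percentages.

Training minimizes weighted cross-entropy with AdamW (default initial
learning rate 0.003, batch size 2, cosine learning-rate decay) and early
stopping on the validation loss.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .pcio import LabeledPointCloud
from .segnet import SegModel


# ------------------------------------------------------------- augmentation

@dataclass
class AugmentConfig:
    shift_range: float = 0.5       # meters, per axis
    scale_lo: float = 0.8
    scale_hi: float = 1.2
    enable_shift: bool = True
    enable_scale: bool = True
    enable_flip: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shift_range < 0:
            raise ValueError("shift_range must be nonnegative")
        if not (0 < self.scale_lo <= self.scale_hi):
            raise ValueError("need 0 < scale_lo <= scale_hi")


def center_shift(cloud: LabeledPointCloud, shift_range: float = 0.5,
                 seed: int = 0) -> LabeledPointCloud:
    """Rigid translation by one vector drawn uniformly from
    ``[-shift_range, shift_range]^3``."""
    if shift_range < 0:
        raise ValueError("shift_range must be nonnegative")
    rng = np.random.default_rng(seed)
    u = rng.uniform(-shift_range, shift_range, size=3)
    return LabeledPointCloud(coords=cloud.coords + u, labels=cloud.labels,
                             features=cloud.features, name=cloud.name)


def random_scale(cloud: LabeledPointCloud, lo: float = 0.8, hi: float = 1.2,
                 seed: int = 0) -> LabeledPointCloud:
    """Isotropic scaling about the centroid by one factor ``s ~ U[lo, hi]``."""
    if not (0 < lo <= hi):
        raise ValueError("need 0 < lo <= hi")
    rng = np.random.default_rng(seed)
    s = rng.uniform(lo, hi)
    centroid = cloud.coords.mean(axis=0)
    return LabeledPointCloud(coords=centroid + s * (cloud.coords - centroid),
                             labels=cloud.labels, features=cloud.features,
                             name=cloud.name)


def random_flip_xz(cloud: LabeledPointCloud, seed: int = 0,
                   force: bool | None = None) -> LabeledPointCloud:
    """With probability 1/2 (or forced), reflect y through the centroid's XZ
    plane. An involution when forced."""
    rng = np.random.default_rng(seed)
    do_flip = bool(rng.integers(2)) if force is None else force
    if not do_flip:
        return cloud
    coords = cloud.coords.copy()
    cy = coords[:, 1].mean()
    coords[:, 1] = 2 * cy - coords[:, 1]
    return LabeledPointCloud(coords=coords, labels=cloud.labels,
                             features=cloud.features, name=cloud.name)


def apply_augmentations(cloud: LabeledPointCloud, cfg: AugmentConfig,
                        seed: int) -> LabeledPointCloud:
    if cfg.enable_shift:
        cloud = center_shift(cloud, cfg.shift_range, seed=seed)
    if cfg.enable_scale:
        cloud = random_scale(cloud, cfg.scale_lo, cfg.scale_hi, seed=seed + 1)
    if cfg.enable_flip:
        cloud = random_flip_xz(cloud, seed=seed + 2)
    return cloud


# ----------------------------------------------------------------- metrics

@dataclass
class ConfusionCounts:
    """One-vs-rest counts per class; ``per_class[c] = (TP, TN, FP, FN)``."""

    per_class: dict[int, tuple[int, int, int, int]]
    n_points: int


@dataclass
class Metrics:
    iou_leaf: float
    iou_stem: float
    acc_leaf: float
    acc_stem: float
    miou: float
    macc: float


def confusion_counts(true_labels: np.ndarray, pred_labels: np.ndarray,
                     n_classes: int = 2) -> ConfusionCounts:
    true_labels = np.asarray(true_labels)
    pred_labels = np.asarray(pred_labels)
    if true_labels.shape != pred_labels.shape:
        raise ValueError("true and predicted label arrays differ in length")
    n = true_labels.size
    per_class = {}
    for c in range(n_classes):
        t = true_labels == c
        p = pred_labels == c
        tp = int(np.sum(t & p))
        fp = int(np.sum(~t & p))
        fn = int(np.sum(t & ~p))
        per_class[c] = (tp, n - tp - fp - fn, fp, fn)
    return ConfusionCounts(per_class=per_class, n_points=n)


def mean_iou(iou_leaf: float, iou_stem: float) -> float:
    """Two-class mIoU: the plain mean of the leaf and stem IoUs."""
    return (iou_leaf + iou_stem) / 2.0


def mean_acc(acc_leaf: float, acc_stem: float) -> float:
    """Two-class mAcc: the plain mean of the leaf and stem accuracies."""
    return (acc_leaf + acc_stem) / 2.0


def compute_metrics(counts: ConfusionCounts) -> Metrics:
    """Per-class Acc/IoU and their means, as percentages. A class absent from
    both truth and prediction has vacuous IoU 100 (with a warning)."""
    if counts.n_points == 0:
        raise ValueError("cannot compute metrics on zero points")
    vals = {}
    for c, (tp, tn, fp, fn) in counts.per_class.items():
        acc = 100.0 * (tp + tn) / (tp + tn + fp + fn)
        denom = tp + fp + fn
        if denom == 0:
            warnings.warn(f"class {c} absent from truth and prediction; "
                          "IoU vacuously 100")
            iou = 100.0
        else:
            iou = 100.0 * tp / denom
        vals[c] = (iou, acc)
    iou_leaf, acc_leaf = vals[0]
    iou_stem, acc_stem = vals[1]
    return Metrics(iou_leaf=iou_leaf, iou_stem=iou_stem,
                   acc_leaf=acc_leaf, acc_stem=acc_stem,
                   miou=mean_iou(iou_leaf, iou_stem),
                   macc=mean_acc(acc_leaf, acc_stem))


# ------------------------------------------------------------------ splits

def split_dataset(manifest: list[dict], scheme: str = "holdout_cultivar",
                  seed: int = 0) -> tuple[list[dict], list[dict], list[dict]]:
    """Disjoint train/val/test split of a manifest of cloud records.

    ``holdout_cultivar`` reserves one cultivar's full growth cycle for test
    and a second for validation; ``holdout_plant`` does the same with plant
    ids (full time series per plant).
    """
    key = {"holdout_cultivar": "cultivar", "holdout_plant": "plant_id"}.get(scheme)
    if key is None:
        raise ValueError(f"unknown split scheme {scheme!r}")
    groups = sorted({rec[key] for rec in manifest})
    if len(groups) < 3:
        raise ValueError(f"need at least 3 distinct {key} groups, got {len(groups)}")
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(groups), size=2, replace=False)
    test_g, val_g = groups[picks[0]], groups[picks[1]]
    test = [r for r in manifest if r[key] == test_g]
    val = [r for r in manifest if r[key] == val_g]
    train = [r for r in manifest if r[key] not in (test_g, val_g)]
    return train, val, test


# ---------------------------------------------------------------- training

@dataclass
class TrainConfig:
    lr: float = 0.003
    weight_decay: float = 0.01
    batch_size: int = 2
    lr_decay: str = "cosine"          # or "step"
    step_decay_every: int = 50
    step_decay_factor: float = 0.5
    early_stop_patience: int = 20
    min_delta: float = 1e-4
    max_epochs: int = 200
    class_weights: str = "inverse_frequency"  # or "uniform"
    augment: AugmentConfig | None = None
    val_every: int = 1
    target_train_macc: float | None = None  # optional early exit on train mAcc
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.early_stop_patience < 1:
            raise ValueError("patience must be >= 1")


def _epoch_lr(cfg: TrainConfig, epoch: int) -> float:
    if cfg.lr_decay == "cosine":
        return cfg.lr * 0.5 * (1 + np.cos(np.pi * epoch / max(cfg.max_epochs, 1)))
    if cfg.lr_decay == "step":
        return cfg.lr * cfg.step_decay_factor ** (epoch // cfg.step_decay_every)
    raise ValueError(f"unknown lr_decay {cfg.lr_decay!r}")


def _class_weight_vector(clouds: list[LabeledPointCloud],
                         mode: str, n_classes: int) -> np.ndarray:
    if mode == "uniform":
        return np.ones(n_classes)
    counts = np.zeros(n_classes)
    for c in clouds:
        counts += np.bincount(c.labels, minlength=n_classes)
    freq = counts / counts.sum()
    w = 1.0 / np.maximum(freq, 1e-6)
    return w / w.mean()


def _eval_clouds(model: SegModel, clouds: list[LabeledPointCloud],
                 class_weights: np.ndarray) -> tuple[float, Metrics]:
    losses, preds, trues = [], [], []
    for c in clouds:
        logits = model.forward(c.coords)
        loss, _ = ag.softmax_cross_entropy(logits, c.labels, class_weights)
        losses.append(loss)
        preds.append(np.argmax(logits.value, axis=1))
        trues.append(c.labels)
    m = compute_metrics(confusion_counts(np.concatenate(trues),
                                         np.concatenate(preds)))
    return float(np.mean(losses)), m


def train_model(model: SegModel, train_clouds: list[LabeledPointCloud],
                val_clouds: list[LabeledPointCloud] | None = None,
                config: TrainConfig | None = None
                ) -> tuple[SegModel, list[dict]]:
    """Fit the model by weighted cross-entropy; returns the best-validation
    checkpoint (by val loss) and the per-epoch history.

    History rows carry epoch, lr, train_loss, val_loss, val_miou, val_macc
    (and train mAcc/mIoU of the epoch's predictions). Early stopping fires
    when the val loss has not improved by ``min_delta`` for
    ``early_stop_patience`` epochs. Fully deterministic per seed.
    """
    cfg = config or TrainConfig()
    if not train_clouds:
        raise ValueError("empty training set")
    for c in train_clouds + (val_clouds or []):
        if c.labels is None:
            raise ValueError(f"cloud {c.name!r} has no labels")
    n_classes = model.config.n_classes
    cw = _class_weight_vector(train_clouds, cfg.class_weights, n_classes)
    opt = ag.AdamW(model.params, lr=cfg.lr, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    history: list[dict] = []
    best_val = np.inf
    best_state = model.state_copy()
    since_improve = 0
    for epoch in range(cfg.max_epochs):
        lr = _epoch_lr(cfg, epoch)
        order = rng.permutation(len(train_clouds))
        epoch_losses = []
        preds, trues = [], []
        for b0 in range(0, len(order), cfg.batch_size):
            batch = order[b0:b0 + cfg.batch_size]
            opt.zero_grad()
            for ci in batch:
                cloud = train_clouds[ci]
                if cfg.augment is not None:
                    aug_seed = int(rng.integers(2 ** 31))
                    cloud = apply_augmentations(cloud, cfg.augment, aug_seed)
                logits = model.forward(cloud.coords)
                loss, grad = ag.softmax_cross_entropy(logits, cloud.labels, cw)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}, "
                        f"cloud {cloud.name!r}: {loss}")
                logits.backward(grad / len(batch))
                epoch_losses.append(loss)
                preds.append(np.argmax(logits.value, axis=1))
                trues.append(train_clouds[ci].labels)
            opt.step(lr=lr)
        train_m = compute_metrics(confusion_counts(np.concatenate(trues),
                                                   np.concatenate(preds)))
        row = {"epoch": epoch, "lr": lr,
               "train_loss": float(np.mean(epoch_losses)),
               "train_macc": train_m.macc, "train_miou": train_m.miou,
               "val_loss": np.nan, "val_miou": np.nan, "val_macc": np.nan}
        if val_clouds and epoch % cfg.val_every == 0:
            val_loss, val_m = _eval_clouds(model, val_clouds, cw)
            row.update(val_loss=val_loss, val_miou=val_m.miou,
                       val_macc=val_m.macc)
            if val_loss < best_val - cfg.min_delta:
                best_val = val_loss
                best_state = model.state_copy()
                since_improve = 0
            else:
                since_improve += 1
        history.append(row)
        if (cfg.target_train_macc is not None
                and train_m.macc >= cfg.target_train_macc):
            break
        if val_clouds and since_improve >= cfg.early_stop_patience:
            break
    if val_clouds:
        model.load_state(best_state)
    return model, history


def evaluate_model(model: SegModel, clouds: list[LabeledPointCloud]
                   ) -> tuple[list[Metrics], Metrics]:
    """Per-cloud metrics plus the unweighted macro-average across clouds."""
    per_cloud = []
    for c in clouds:
        if c.labels is None:
            raise ValueError(f"cloud {c.name!r} has no labels")
        logits = model.forward(c.coords)
        pred = np.argmax(logits.value, axis=1)
        per_cloud.append(compute_metrics(confusion_counts(c.labels, pred)))
    agg = Metrics(
        iou_leaf=float(np.mean([m.iou_leaf for m in per_cloud])),
        iou_stem=float(np.mean([m.iou_stem for m in per_cloud])),
        acc_leaf=float(np.mean([m.acc_leaf for m in per_cloud])),
        acc_stem=float(np.mean([m.acc_stem for m in per_cloud])),
        miou=float(np.mean([m.miou for m in per_cloud])),
        macc=float(np.mean([m.macc for m in per_cloud])),
    )
    return per_cloud, agg
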
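"""Training: pixel-wise BCE (plus Dice/focal ablation losses), Adam with a
plateau-halving learning-rate schedule, and patch-wise inference stitched
back to full frames.

The reference recipe is Adam at 1e-3, batch size 16, 40 epochs; the
learning rate halves after 5 epochs without validation-loss improvement
and never drops below 1e-5.  Training is deterministic under a fixed seed
(single numpy stream for shuffling; seeded weight init) on a fixed
platform.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from masegnet import nn
from masegnet.nn.autograd import power
from masegnet.model import CbamAgUNet
from masegnet.preprocess import PatchSet, extract_patches, stitch_patches

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "ReduceLROnPlateau",
    "bce_loss",
    "dice_loss",
    "focal_loss",
    "train",
    "predict",
]

EPS = 1e-7  # probability clamp for log stability

LOSSES = ("bce", "dice", "focal")


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 16
    epochs: int = 40
    lr_init: float = 1e-3
    lr_factor: float = 0.5
    lr_patience: int = 5
    lr_floor: float = 1e-5
    loss: str = "bce"
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr_floor > self.lr_init:
            raise ValueError("lr_floor must not exceed lr_init")
        if self.lr_patience < 1:
            raise ValueError("lr_patience must be >= 1")
        if self.loss not in LOSSES:
            raise ValueError(f"loss must be one of {LOSSES}, got {self.loss!r}")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in [0, 1)")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)

    def append(self, tl, ta, vl, va, lr) -> None:
        self.train_loss.append(float(tl))
        self.train_accuracy.append(float(ta))
        self.val_loss.append(float(vl))
        self.val_accuracy.append(float(va))
        self.learning_rate.append(float(lr))

    def __len__(self) -> int:
        return len(self.train_loss)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["epoch", "train_loss", "train_accuracy",
                        "val_loss", "val_accuracy", "learning_rate"])
            for i in range(len(self)):
                w.writerow([i + 1, self.train_loss[i], self.train_accuracy[i],
                            self.val_loss[i], self.val_accuracy[i],
                            self.learning_rate[i]])


# losses --------------------------------------------------------------------

def bce_loss(pred: nn.Tensor, target: np.ndarray) -> nn.Tensor:
    """Mean binary cross-entropy over all pixels,
    L = -(1/K) sum_i [p_i log q_i + (1 - p_i) log(1 - q_i)],
    with q clamped to [1e-7, 1 - 1e-7]."""
    p = np.asarray(target, dtype=np.float32)
    if pred.shape != p.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs target {p.shape}")
    q = nn.clip(pred, EPS, 1.0 - EPS)
    per_pixel = p * nn.log(q) + (1.0 - p) * nn.log(1.0 - q)
    return -nn.mean(per_pixel)


def dice_loss(pred: nn.Tensor, target: np.ndarray,
              smooth: float = 1.0) -> nn.Tensor:
    """1 - soft Dice, with probabilistic (soft) intersection/size counts."""
    p = np.asarray(target, dtype=np.float32)
    if pred.shape != p.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs target {p.shape}")
    inter = nn.sum_(pred * p)
    total = nn.sum_(pred) + float(p.sum())
    soft_dice = (2.0 * inter + smooth) * power(total + smooth, -1.0)
    return 1.0 - soft_dice


def focal_loss(pred: nn.Tensor, target: np.ndarray, gamma: float = 2.0,
               alpha: float = 0.25) -> nn.Tensor:
    """Focal BCE with the standard gamma=2, alpha=0.25 defaults."""
    p = np.asarray(target, dtype=np.float32)
    if pred.shape != p.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs target {p.shape}")
    q = nn.clip(pred, EPS, 1.0 - EPS)
    pos = alpha * power(1.0 - q, gamma) * nn.log(q) * p
    neg = (1.0 - alpha) * power(q, gamma) * nn.log(1.0 - q) * (1.0 - p)
    return -nn.mean(pos + neg)


_LOSS_FUNCS = {"bce": bce_loss, "dice": dice_loss, "focal": focal_loss}


# learning-rate schedule ----------------------------------------------------

class ReduceLROnPlateau:
    """Halve the learning rate after `patience` epochs without improvement
    of the monitored loss, never below `floor`.

    Improvement means a decrease by more than `min_delta` over the best
    loss seen so far; the stagnation counter resets on improvement and on
    each reduction.
    """

    def __init__(self, optimizer, factor: float = 0.5, patience: int = 5,
                 floor: float = 1e-5, min_delta: float = 1e-4):
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.floor = floor
        self.min_delta = min_delta
        self.best: float | None = None
        self.stagnant = 0

    @property
    def lr(self) -> float:
        return self.optimizer.lr

    def step(self, val_loss: float) -> float:
        if self.best is not None and val_loss < self.best - self.min_delta:
            self.best = val_loss
            self.stagnant = 0
        else:
            if self.best is None or val_loss < self.best:
                self.best = val_loss
            self.stagnant += 1
            if self.stagnant >= self.patience:
                self.optimizer.lr = max(self.optimizer.lr * self.factor,
                                        self.floor)
                self.stagnant = 0
        return self.optimizer.lr


# training loop -------------------------------------------------------------

def _as_batch(patches: list[np.ndarray]) -> np.ndarray:
    """Stack HxW (or HxWxC) patches into a B x C x H x W float batch
    scaled to [0, 1]."""
    arrs = []
    for p in patches:
        a = np.asarray(p, dtype=np.float32)
        if a.ndim == 2:
            a = a[None]
        else:
            a = a.transpose(2, 0, 1)
        arrs.append(a)
    return np.stack(arrs) / 255.0


def _mask_batch(masks: list[np.ndarray]) -> np.ndarray:
    arrs = [np.asarray(m, dtype=np.float32)[None] for m in masks]
    return np.stack(arrs)


def _soft_dice_np(prob: np.ndarray, target: np.ndarray,
                  threshold: float = 0.5) -> float:
    pred = prob >= threshold
    t = target > 0.5
    inter = np.logical_and(pred, t).sum()
    denom = pred.sum() + t.sum()
    return 1.0 if denom == 0 else 2.0 * inter / denom


def _epoch_pass(model, xs, ys, config, optimizer=None):
    """One pass over (xs, ys); trains if an optimizer is given.  Returns
    (mean loss, pixel accuracy)."""
    loss_fn = _LOSS_FUNCS[config.loss]
    n = xs.shape[0]
    total_loss = 0.0
    correct = 0
    for start in range(0, n, config.batch_size):
        xb = xs[start:start + config.batch_size]
        yb = ys[start:start + config.batch_size]
        if optimizer is None:
            prob = model.predict_proba(xb)
            loss_val = float(
                loss_fn(nn.Tensor(prob), yb).item())
        else:
            optimizer.zero_grad()
            pred = model(nn.Tensor(xb))
            loss = loss_fn(pred, yb)
            loss.backward()
            optimizer.step()
            prob = pred.data
            loss_val = loss.item()
        total_loss += loss_val * xb.shape[0]
        correct += ((prob >= 0.5) == (yb > 0.5)).sum()
    accuracy = correct / ys.size
    return total_loss / n, accuracy


def train(model: CbamAgUNet, train_patches, train_masks,
          config: TrainConfig = TrainConfig(), *,
          val_patches=None, val_masks=None,
          checkpoint_path: str | Path | None = None,
          stop_train_dice: float | None = None
          ) -> tuple[CbamAgUNet, TrainHistory]:
    """Train on aligned patch/mask lists.

    When no validation pairs are supplied, `val_fraction` of the training
    pairs is held out (seeded shuffle) to drive the plateau schedule — the
    test set is never used for scheduling.  The best-validation weights
    are restored at the end (and written to `checkpoint_path` if given).
    ``stop_train_dice`` ends training early once the training-set Dice at
    threshold 0.5 reaches the given value (used by capacity checks).
    """
    train_patches, train_masks = list(train_patches), list(train_masks)
    if len(train_patches) == 0 or len(train_patches) != len(train_masks):
        raise ValueError("need equal, non-zero numbers of patches and masks")
    xs_all = _as_batch(train_patches)
    ys_all = _mask_batch(train_masks)

    rng = np.random.default_rng(config.seed)
    if val_patches is not None:
        xs, ys = xs_all, ys_all
        vxs, vys = _as_batch(list(val_patches)), _mask_batch(list(val_masks))
    else:
        order = rng.permutation(xs_all.shape[0])
        n_val = int(round(config.val_fraction * xs_all.shape[0]))
        val_idx, train_idx = order[:n_val], order[n_val:]
        if train_idx.size == 0:
            raise ValueError("validation split left no training patches")
        xs, ys = xs_all[train_idx], ys_all[train_idx]
        vxs, vys = xs_all[val_idx], ys_all[val_idx]
    has_val = vxs.shape[0] > 0

    optimizer = nn.Adam(model.parameters(), lr=config.lr_init)
    scheduler = ReduceLROnPlateau(optimizer, factor=config.lr_factor,
                                  patience=config.lr_patience,
                                  floor=config.lr_floor)
    history = TrainHistory()
    best_val = np.inf
    best_state = model.state_dict()

    for _ in range(config.epochs):
        order = rng.permutation(xs.shape[0])
        train_loss, train_acc = _epoch_pass(
            model, xs[order], ys[order], config, optimizer)
        if has_val:
            val_loss, val_acc = _epoch_pass(model, vxs, vys, config)
        else:
            val_loss, val_acc = train_loss, train_acc
        lr_now = scheduler.lr
        history.append(train_loss, train_acc, val_loss, val_acc, lr_now)
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_dict()
        scheduler.step(val_loss)
        if stop_train_dice is not None:
            prob = np.concatenate(
                [model.predict_proba(xs[i:i + config.batch_size])
                 for i in range(0, xs.shape[0], config.batch_size)])
            if _soft_dice_np(prob, ys) >= stop_train_dice:
                best_state = model.state_dict()
                break

    model.load_state_dict(best_state)
    if checkpoint_path is not None:
        from masegnet.model import save_checkpoint
        save_checkpoint(model, checkpoint_path)
    return model, history


def predict(model: CbamAgUNet, image: np.ndarray,
            patch_size: int = 64, batch_size: int = 16) -> np.ndarray:
    """Full-frame probability map by patch-wise inference.

    The (preprocessed, single-channel, [0, 255]) image is cut into the
    non-overlapping patch grid, each patch runs through the network, and
    the per-patch maps are stitched back by their grid coordinates.
    """
    pset = extract_patches(np.asarray(image), patch_size)
    xs = _as_batch(pset.patches)
    probs = []
    for start in range(0, xs.shape[0], batch_size):
        out = model.predict_proba(xs[start:start + batch_size])
        probs.extend(out[:, 0])
    prob_set = PatchSet(patches=[p.astype(np.float64) for p in probs],
                        coords=pset.coords, source_size=pset.source_size,
                        patch_size=patch_size)
    return stitch_patches(prob_set)
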
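"""Pixel-level segmentation metrics: confusion counts, accuracy, the
threshold-swept ROC with trapezoidal AUC, Dice and IoU.

Dice is implemented in its overlap form 2TP / (2TP + FP + FN), which is
algebraically identical to the precision-sensitivity form
2 (P x SE) / (P + SE); both are exposed so the identity can be asserted.
Aggregation over a test set is micro (global pixel sums) with a per-image
breakdown alongside, because with lesions occupying well under 1% of
pixels a per-image average would be dominated by lesion-free frames.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_counts",
    "accuracy",
    "roc_auc",
    "dice",
    "dice_precision_sensitivity",
    "iou",
    "evaluate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


@dataclass
class MetricsReport:
    accuracy: float
    dice: float
    iou: float
    auc: float
    threshold: float
    counts: ConfusionCounts
    tpr_curve: list[float] = field(default_factory=list)
    fpr_curve: list[float] = field(default_factory=list)
    per_image: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = asdict(self)
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, text: str) -> "MetricsReport":
        payload = json.loads(text)
        payload["counts"] = ConfusionCounts(**payload["counts"])
        return cls(**payload)


def _check_binary(arr: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(arr)
    vals = np.unique(a)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"{name} must be binary (0/1); found values {vals[:5]}")
    return a.astype(bool)


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Exact pixel tallies of TP / TN / FP / FN."""
    p = _check_binary(pred, "pred")
    t = _check_binary(truth, "truth")
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    tp = int(np.count_nonzero(p & t))
    tn = int(np.count_nonzero(~p & ~t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    return ConfusionCounts(tp, tn, fp, fn)


def accuracy(counts: ConfusionCounts) -> float:
    """(TP + TN) / (TP + FP + FN + TN)."""
    if counts.total == 0:
        raise ValueError("empty confusion counts")
    return (counts.tp + counts.tn) / counts.total


def dice(pred: np.ndarray, truth: np.ndarray) -> float:
    """2 |G n S| / (|G| + |S|); 1.0 when both masks are empty."""
    c = confusion_counts(pred, truth)
    denom = 2 * c.tp + c.fp + c.fn
    return 1.0 if denom == 0 else 2 * c.tp / denom


def dice_precision_sensitivity(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice in its 2 (P x SE) / (P + SE) form — identical to `dice` but
    computed through precision and sensitivity, kept for the identity
    check."""
    c = confusion_counts(pred, truth)
    if 2 * c.tp + c.fp + c.fn == 0:
        return 1.0
    if c.tp == 0:
        return 0.0
    precision = c.tp / (c.tp + c.fp)
    sensitivity = c.tp / (c.tp + c.fn)
    return 2 * precision * sensitivity / (precision + sensitivity)


def iou(pred: np.ndarray, truth: np.ndarray) -> float:
    """|G n S| / |G u S|; 1.0 when both masks are empty."""
    c = confusion_counts(pred, truth)
    union = c.tp + c.fp + c.fn
    return 1.0 if union == 0 else c.tp / union


def roc_auc(prob_map: np.ndarray, truth: np.ndarray,
            n_thresholds: int = 256
            ) -> tuple[np.ndarray, np.ndarray, float]:
    """Threshold-swept ROC and trapezoidal AUC.

    Thresholds are ``n_thresholds`` evenly spaced values in [0, 1] plus
    the empirical score set when it has at most 1e4 unique values; the
    curve always includes the (0,0) and (1,1) endpoints.
    """
    scores = np.asarray(prob_map, dtype=float).ravel()
    t = _check_binary(truth, "truth").ravel()
    if t.shape != scores.shape:
        raise ValueError(f"shape mismatch: {scores.shape} vs {t.shape}")
    n_pos = int(t.sum())
    n_neg = t.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC undefined: truth contains a single class")

    thresholds = np.linspace(0.0, 1.0, n_thresholds)
    uniq = np.unique(scores)
    if uniq.size <= 10_000:
        thresholds = np.union1d(thresholds, uniq)

    # predicted positive at threshold th means score >= th
    pos_scores = np.sort(scores[t])
    neg_scores = np.sort(scores[~t])
    tp = n_pos - np.searchsorted(pos_scores, thresholds, side="left")
    fp = n_neg - np.searchsorted(neg_scores, thresholds, side="left")
    tpr = tp / n_pos
    fpr = fp / n_neg

    fpr_curve = np.concatenate(([0.0], fpr, [1.0]))
    tpr_curve = np.concatenate(([0.0], tpr, [1.0]))
    order = np.lexsort((tpr_curve, fpr_curve))
    fpr_curve, tpr_curve = fpr_curve[order], tpr_curve[order]
    auc = float(np.trapezoid(tpr_curve, fpr_curve))
    return tpr_curve, fpr_curve, auc


def evaluate(model, test_images, test_masks, threshold: float = 0.5,
             patch_size: int = 64) -> MetricsReport:
    """Micro-aggregated pixel metrics of a model over preprocessed
    image/mask pairs, plus a per-image breakdown.

    ``test_images`` are single-channel preprocessed frames in [0, 255];
    probability maps come from patch-wise inference.  Accuracy/Dice/IoU
    use binarisation at ``threshold``; the ROC uses the raw
    probabilities.
    """
    from masegnet.train import predict

    images = list(test_images)
    masks = list(test_masks)
    if len(images) == 0 or len(images) != len(masks):
        raise ValueError("need equal, non-zero numbers of images and masks")

    total = ConfusionCounts(0, 0, 0, 0)
    per_image = []
    all_probs, all_truth = [], []
    for i, (img, msk) in enumerate(zip(images, masks)):
        prob = predict(model, img, patch_size=patch_size)
        truth = (np.asarray(msk) > 0.5).astype(np.uint8)
        # crop truth to the stitched grid (residual margins are dropped)
        truth = truth[: prob.shape[0], : prob.shape[1]]
        pred = (prob >= threshold).astype(np.uint8)
        c = confusion_counts(pred, truth)
        total = total + c
        per_image.append({
            "index": i,
            "dice": dice(pred, truth),
            "iou": iou(pred, truth),
            "accuracy": accuracy(c),
        })
        all_probs.append(prob.ravel())
        all_truth.append(truth.ravel())

    probs = np.concatenate(all_probs)
    truths = np.concatenate(all_truth)
    tpr, fpr, auc = roc_auc(probs, truths)
    micro_denom = 2 * total.tp + total.fp + total.fn
    micro_dice = 1.0 if micro_denom == 0 else 2 * total.tp / micro_denom
    micro_union = total.tp + total.fp + total.fn
    micro_iou = 1.0 if micro_union == 0 else total.tp / micro_union
    return MetricsReport(
        accuracy=accuracy(total),
        dice=micro_dice,
        iou=micro_iou,
        auc=auc,
        threshold=threshold,
        counts=total,
        tpr_curve=tpr.tolist(),
        fpr_curve=fpr.tolist(),
        per_image=per_image,
    )
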
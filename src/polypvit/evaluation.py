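"""Segmentation metrics and the k-fold cross-validation harness.

Pixel metrics (accuracy, sensitivity, specificity, precision) come from the
confusion counts with polyp as the positive class.  Overlap metrics are Dice
= 2|M n G| / (|M| + |G|), IoU = |M n G| / |M u G| for the polyp label, and
weighted IoU = the per-label IoU weighted by each label's ground-truth pixel
frequency.  Conventions the source leaves open, fixed here:

* a ratio with denominator zero (e.g. sensitivity when G has no positives
  and none are predicted) returns 1 and is flagged as vacuous, keeping fold
  averages well-defined on polyp-free images;
* empty-vs-empty overlaps count as 1;
* fold dispersion is the population (not sample) standard deviation;
* per-fold metrics are image-averaged, not pixel-pooled.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_io import make_splits
from .synthetic import LabeledImage

__all__ = [
    "ConfusionCounts",
    "MetricsRecord",
    "confusion_counts",
    "pixel_metrics",
    "overlap_metrics",
    "evaluate_pairs",
    "crossval_evaluate",
    "METRIC_COLUMNS",
]

METRIC_COLUMNS = ("accuracy", "sensitivity", "specificity", "precision",
                  "weighted_iou", "dice")


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _check_binary(mask: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(mask)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must be binary (values in {{0, 1}})")
    return arr.astype(bool)


def confusion_counts(predicted, truth) -> ConfusionCounts:
    """Pixelwise TP/TN/FP/FN with polyp (label 1) as positive."""
    m = _check_binary(predicted, "predicted mask")
    g = _check_binary(truth, "ground truth mask")
    if m.shape != g.shape:
        raise ValueError(f"shape mismatch: {m.shape} vs {g.shape}")
    return ConfusionCounts(
        tp=int(np.logical_and(m, g).sum()),
        tn=int(np.logical_and(~m, ~g).sum()),
        fp=int(np.logical_and(m, ~g).sum()),
        fn=int(np.logical_and(~m, g).sum()),
    )


def _ratio(num: int, den: int, flags: list[str], name: str) -> float:
    if den == 0:
        flags.append(name)
        return 1.0
    return num / den


def pixel_metrics(counts: ConfusionCounts) -> dict:
    """Accuracy, sensitivity, specificity, precision (+ vacuous-ratio flags)."""
    flags: list[str] = []
    out = {
        "accuracy": _ratio(counts.tp + counts.tn, counts.total, flags, "accuracy"),
        "sensitivity": _ratio(counts.tp, counts.tp + counts.fn, flags, "sensitivity"),
        "specificity": _ratio(counts.tn, counts.tn + counts.fp, flags, "specificity"),
        "precision": _ratio(counts.tp, counts.tp + counts.fp, flags, "precision"),
    }
    out["vacuous"] = tuple(flags)
    return out


def _label_iou(m: np.ndarray, g: np.ndarray) -> float:
    inter = np.logical_and(m, g).sum()
    union = np.logical_or(m, g).sum()
    return 1.0 if union == 0 else inter / union


def overlap_metrics(predicted, truth) -> dict:
    """Dice, IoU (polyp label) and ground-truth-frequency-weighted IoU."""
    m = _check_binary(predicted, "predicted mask")
    g = _check_binary(truth, "ground truth mask")
    if m.shape != g.shape:
        raise ValueError(f"shape mismatch: {m.shape} vs {g.shape}")
    inter = np.logical_and(m, g).sum()
    size_sum = m.sum() + g.sum()
    dice = 1.0 if size_sum == 0 else 2.0 * inter / size_sum
    iou = _label_iou(m, g)
    total = g.size
    w_polyp = g.sum() / total
    weighted = w_polyp * iou + (1.0 - w_polyp) * _label_iou(~m, ~g)
    return {"dice": float(dice), "iou": float(iou), "weighted_iou": float(weighted)}


def image_metrics(predicted, truth) -> dict:
    """All six reported metrics for one mask pair."""
    pm = pixel_metrics(confusion_counts(predicted, truth))
    om = overlap_metrics(predicted, truth)
    return {
        "accuracy": pm["accuracy"],
        "sensitivity": pm["sensitivity"],
        "specificity": pm["specificity"],
        "precision": pm["precision"],
        "weighted_iou": om["weighted_iou"],
        "dice": om["dice"],
    }


def evaluate_pairs(predict_fn, pairs: list[LabeledImage]) -> dict:
    """Image-averaged metrics of ``predict_fn(image_hwc) -> mask`` over pairs."""
    rows = [image_metrics(predict_fn(p.image), np.asarray(p.mask)) for p in pairs]
    return {k: float(np.mean([r[k] for r in rows])) for k in METRIC_COLUMNS}


@dataclass
class MetricsRecord:
    """Per-fold metric values with mean and population sd per metric."""

    folds: list[dict] = field(default_factory=list)

    @property
    def mean(self) -> dict:
        return {k: float(np.mean([f[k] for f in self.folds])) for k in METRIC_COLUMNS}

    @property
    def sd(self) -> dict:
        return {k: float(np.std([f[k] for f in self.folds])) for k in METRIC_COLUMNS}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"folds": self.folds, "mean": self.mean, "sd": self.sd}, indent=2))

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(("fold",) + METRIC_COLUMNS)
            for i, row in enumerate(self.folds):
                writer.writerow([i] + [f"{row[k]:.6f}" for k in METRIC_COLUMNS])
            mean, sd = self.mean, self.sd
            writer.writerow(["mean±sd"] + [f"{mean[k]:.4f}±{sd[k]:.4f}"
                                           for k in METRIC_COLUMNS])


def crossval_evaluate(model_builder, dataset: list[LabeledImage], k: int,
                      config, seed: int = 0, verbose: bool = False) -> MetricsRecord:
    """Train/evaluate once per fold with disjoint test folds.

    ``model_builder(config, seed)`` must return an object exposing
    ``fit(pairs)`` and ``predict_mask(image_hwc) -> mask``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(dataset) < k:
        raise ValueError(f"dataset of {len(dataset)} items cannot form {k} folds")
    splits = make_splits(len(dataset), ratio=0.8, k=k, seed=seed)
    record = MetricsRecord()
    for f, test_idx in enumerate(splits.folds):
        test_set = set(int(i) for i in test_idx)
        train_pairs = [dataset[i] for i in range(len(dataset)) if i not in test_set]
        test_pairs = [dataset[i] for i in sorted(test_set)]
        predictor = model_builder(config, seed + f)
        predictor.fit(train_pairs)
        fold_metrics = evaluate_pairs(predictor.predict_mask, test_pairs)
        record.folds.append(fold_metrics)
        if verbose:
            print(f"fold {f}: " + "  ".join(
                f"{k_}={v:.4f}" for k_, v in fold_metrics.items()))
    return record
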
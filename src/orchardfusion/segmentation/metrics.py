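"""Segmentation accuracy metrics: PA, per-class accuracy, IoU, mIoU.

All metrics derive from the n_classes x n_classes confusion matrix C where
C[t, p] counts pixels of true class t predicted as p:

    PA       = trace(C) / sum(C)
    Acc_c    = C[c, c] / row_c            (per-class recall)
    AccClass = mean over classes with row_c > 0 of Acc_c
    IoU_c    = C[c, c] / (row_c + col_c - C[c, c])
    mIoU     = unweighted mean IoU over classes present in truth or prediction
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SegMetrics", "confusion_matrix", "evaluate_segmentation"]


@dataclass
class SegMetrics:
    pixel_accuracy: float
    class_accuracy: float
    per_class_iou: dict = field(default_factory=dict)
    miou: float = 0.0
    confusion: np.ndarray | None = None

    def to_dict(self):
        return {
            "PA": self.pixel_accuracy,
            "AccClass": self.class_accuracy,
            "IoU": {int(k): float(v) for k, v in self.per_class_iou.items()},
            "MIoU": self.miou,
        }


def confusion_matrix(pred_masks, true_masks, n_classes: int) -> np.ndarray:
    """Accumulate the confusion matrix over paired prediction/truth masks."""
    if isinstance(pred_masks, np.ndarray) and pred_masks.ndim == 2:
        pred_masks, true_masks = [pred_masks], [true_masks]
    pred_masks, true_masks = list(pred_masks), list(true_masks)
    if len(pred_masks) == 0:
        raise ValueError("no mask pairs given")
    if len(pred_masks) != len(true_masks):
        raise ValueError("prediction/truth mask counts differ")
    conf = np.zeros((n_classes, n_classes), dtype=np.int64)
    for pred, true in zip(pred_masks, true_masks):
        pred = np.asarray(pred)
        true = np.asarray(true)
        if pred.shape != true.shape:
            raise ValueError(f"mask shape mismatch: {pred.shape} vs {true.shape}")
        if pred.min() < 0 or pred.max() >= n_classes or true.min() < 0 or true.max() >= n_classes:
            raise ValueError("mask labels outside [0, n_classes)")
        idx = true.astype(np.int64).ravel() * n_classes + pred.astype(np.int64).ravel()
        conf += np.bincount(idx, minlength=n_classes * n_classes).reshape(n_classes, n_classes)
    return conf


def evaluate_segmentation(pred_masks, true_masks, n_classes: int) -> SegMetrics:
    conf = confusion_matrix(pred_masks, true_masks, n_classes)
    total = conf.sum()
    diag = np.diag(conf).astype(np.float64)
    rows = conf.sum(axis=1).astype(np.float64)
    cols = conf.sum(axis=0).astype(np.float64)

    pa = float(diag.sum() / total)

    present_truth = rows > 0
    acc_class = float(np.mean(diag[present_truth] / rows[present_truth]))

    # classes absent from both truth and prediction are excluded (0/0 guard)
    present = (rows + cols) > 0
    union = rows + cols - diag
    per_class_iou = {int(c): float(diag[c] / union[c]) for c in np.nonzero(present)[0]}
    miou = float(np.mean([per_class_iou[c] for c in per_class_iou]))

    return SegMetrics(pixel_accuracy=pa, class_accuracy=acc_class,
                      per_class_iou=per_class_iou, miou=miou, confusion=conf)
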
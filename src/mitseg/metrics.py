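"""Confusion matrices and segmentation performance measures.

All metrics derive from a single K x K pixel-count confusion matrix
(rows = ground truth, columns = prediction):

* class-wise accuracy (recall): cm[k,k] / row_sum[k];
* average accuracy: the unweighted (macro) mean of class-wise accuracies
  over classes present in the ground truth — absent classes are excluded,
  not counted as zero;
* per-class IoU: cm[k,k] / (row_sum[k] + col_sum[k] - cm[k,k]), with mIoU
  the macro mean over present classes;
* F1 in micro (= overall pixel accuracy for single-label data), macro and
  support-weighted variants.

``confusion`` is additive over image partitions, which allows streamed
evaluation of tiled predictions.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ConfusionMatrix", "MetricsReport", "confusion",
           "classwise_accuracy", "average_accuracy", "mean_iou", "f1_scores",
           "compute_report"]


@dataclass
class ConfusionMatrix:
    counts: np.ndarray                       # (K, K) int64
    labels: tuple = ()

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("confusion matrix entries must be non-negative")
        if not self.labels:
            self.labels = tuple(str(i) for i in range(self.counts.shape[0]))
        if len(self.labels) != self.counts.shape[0]:
            raise ValueError("labels length must equal matrix size")

    @property
    def K(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def present(self) -> np.ndarray:
        """Boolean vector: class appears in the ground truth."""
        return self.counts.sum(axis=1) > 0

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.K != other.K:
            raise ValueError("cannot add confusion matrices of different size")
        return ConfusionMatrix(self.counts + other.counts, self.labels)

    def save_csv(self, path):
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["true\\pred"] + list(self.labels))
            for name, row in zip(self.labels, self.counts):
                w.writerow([name] + row.tolist())

    def plot(self, path, normalize: bool = True):
        """Write a heatmap PNG of the (optionally row-normalized) matrix."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        m = self.counts.astype(float)
        if normalize:
            rs = m.sum(axis=1, keepdims=True)
            m = np.divide(m, rs, out=np.zeros_like(m), where=rs > 0)
        fig, ax = plt.subplots(figsize=(7, 6))
        im = ax.imshow(m, cmap="viridis", vmin=0)
        ax.set_xticks(range(self.K), self.labels, rotation=90, fontsize=7)
        ax.set_yticks(range(self.K), self.labels, fontsize=7)
        ax.set_xlabel("predicted")
        ax.set_ylabel("ground truth")
        fig.colorbar(im, ax=ax)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def confusion(pred_mask: np.ndarray, true_mask: np.ndarray, K: int = 12,
              validity_mask: np.ndarray | None = None,
              labels: tuple = ()) -> ConfusionMatrix:
    """Pixel-count confusion matrix over valid pixels."""
    pred = np.asarray(pred_mask)
    true = np.asarray(true_mask)
    if pred.shape != true.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs true {true.shape}")
    if validity_mask is not None:
        valid = np.asarray(validity_mask, dtype=bool)
        if valid.shape != true.shape:
            raise ValueError("validity mask shape mismatch")
        pred, true = pred[valid], true[valid]
    pred = pred.ravel().astype(np.int64)
    true = true.ravel().astype(np.int64)
    if pred.size and (pred.max() >= K or true.max() >= K or
                      pred.min() < 0 or true.min() < 0):
        raise ValueError(f"labels must lie in [0, {K})")
    counts = np.bincount(true * K + pred, minlength=K * K).reshape(K, K)
    return ConfusionMatrix(counts, labels)


def classwise_accuracy(cm: ConfusionMatrix) -> np.ndarray:
    """Per-class recall; NaN marks classes absent from the ground truth."""
    rs = cm.counts.sum(axis=1).astype(float)
    diag = np.diag(cm.counts).astype(float)
    return np.divide(diag, rs, out=np.full(cm.K, np.nan), where=rs > 0)


def average_accuracy(cm: ConfusionMatrix) -> float:
    """Macro mean of class-wise accuracies over present classes."""
    acc = classwise_accuracy(cm)
    if np.isnan(acc).all():
        raise ValueError("no class present in ground truth")
    return float(np.nanmean(acc))


def per_class_iou(cm: ConfusionMatrix) -> np.ndarray:
    rs = cm.counts.sum(axis=1).astype(float)
    cs = cm.counts.sum(axis=0).astype(float)
    diag = np.diag(cm.counts).astype(float)
    union = rs + cs - diag
    iou = np.divide(diag, union, out=np.full(cm.K, np.nan), where=union > 0)
    iou[rs == 0] = np.nan  # absent classes are excluded, not zero
    return iou


def mean_iou(cm: ConfusionMatrix) -> float:
    """Macro mean IoU over classes present in the ground truth."""
    iou = per_class_iou(cm)
    if np.isnan(iou).all():
        raise ValueError("no class present in ground truth")
    return float(np.nanmean(iou))


def f1_scores(cm: ConfusionMatrix) -> dict:
    """Micro, macro and support-weighted F1 from the confusion matrix.

    Per-class F1 uses precision = diag/col_sum and recall = diag/row_sum.
    Macro and weighted means run over classes present in the ground truth.
    """
    rs = cm.counts.sum(axis=1).astype(float)
    cs = cm.counts.sum(axis=0).astype(float)
    diag = np.diag(cm.counts).astype(float)
    denom = rs + cs
    f1 = np.divide(2 * diag, denom, out=np.zeros(cm.K), where=denom > 0)
    present = rs > 0
    if not present.any():
        raise ValueError("no class present in ground truth")
    total = rs.sum()
    return {
        "micro": float(diag.sum() / total) if total else 0.0,
        "macro": float(f1[present].mean()),
        "weighted": float((f1[present] * rs[present]).sum() / total),
        "per_class": f1,
    }


@dataclass
class MetricsReport:
    """The full measurement bundle for one evaluation run."""
    confusion_matrix: ConfusionMatrix
    per_class_accuracy: np.ndarray = field(init=False)
    per_class_iou: np.ndarray = field(init=False)
    average_accuracy: float = field(init=False)
    mean_iou: float = field(init=False)
    f1: dict = field(init=False)

    def __post_init__(self):
        cm = self.confusion_matrix
        self.per_class_accuracy = classwise_accuracy(cm)
        self.per_class_iou = per_class_iou(cm)
        self.average_accuracy = average_accuracy(cm)
        self.mean_iou = mean_iou(cm)
        self.f1 = f1_scores(cm)

    def save_csv(self, path):
        cm = self.confusion_matrix
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["metric", "class", "value"])
            for name, acc, iou, f1c in zip(cm.labels, self.per_class_accuracy,
                                           self.per_class_iou,
                                           self.f1["per_class"]):
                w.writerow(["accuracy", name,
                            "" if np.isnan(acc) else f"{acc:.6f}"])
                w.writerow(["iou", name,
                            "" if np.isnan(iou) else f"{iou:.6f}"])
                w.writerow(["f1", name, f"{f1c:.6f}"])
            w.writerow(["average_accuracy", "", f"{self.average_accuracy:.6f}"])
            w.writerow(["mean_iou", "", f"{self.mean_iou:.6f}"])
            for k in ("micro", "macro", "weighted"):
                w.writerow([f"f1_{k}", "", f"{self.f1[k]:.6f}"])


def compute_report(pred_mask, true_mask, K: int = 12,
                   validity_mask=None, labels: tuple = ()) -> MetricsReport:
    return MetricsReport(confusion(pred_mask, true_mask, K, validity_mask,
                                   labels))
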
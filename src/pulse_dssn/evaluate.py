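"""Macro-averaged multiclass metrics and confusion matrices.

The judging index is the macroaverage: the unweighted mean of a per-class
metric over the seven classes, insensitive to class imbalance.  Two
"accuracy" readings are reported because both conventions appear in the
clinical literature: ``accuracy`` (overall fraction correct, trace/total)
and ``mean_per_class_accuracy`` (the average of the per-class recognition
rates, i.e. macro recall / balanced accuracy).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import CLASS_NAMES

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "macro_metrics",
    "confusion_to_csv",
    "plot_confusion",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Count grid: rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_labels: tuple[int, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        k = len(self.class_labels)
        if c.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {c.shape}")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c.astype(int))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_normalized(self) -> np.ndarray:
        """Per-class recognition-rate display form (rows sum to 1)."""
        sums = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(sums > 0, self.counts / sums, 0.0)
        return out


@dataclass(frozen=True)
class MetricsReport:
    macro_precision: float  # "average accuracy rate"
    macro_recall: float  # "average recall rate"
    accuracy: float  # overall fraction correct
    mean_per_class_accuracy: float  # average of per-class recognition rates
    per_class_precision: dict[int, float]
    per_class_recall: dict[int, float]
    confusion: ConfusionMatrix
    undefined_precision_classes: tuple[int, ...] = field(default=())

    def as_dict(self) -> dict:
        return {
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "accuracy": self.accuracy,
            "mean_per_class_accuracy": self.mean_per_class_accuracy,
            "per_class_precision": {int(k): v for k, v in self.per_class_precision.items()},
            "per_class_recall": {int(k): v for k, v in self.per_class_recall.items()},
            "confusion_counts": self.confusion.counts.tolist(),
            "class_labels": list(self.confusion.class_labels),
        }


def confusion(
    true_labels, predicted_labels, class_labels: tuple[int, ...] | None = None
) -> ConfusionMatrix:
    """Tally counts[i][j] = #(true = class i, predicted = class j)."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError("label sequences must be 1-D and of equal length")
    if class_labels is None:
        class_labels = tuple(sorted(CLASS_NAMES))
    lut = {c: i for i, c in enumerate(class_labels)}
    unknown = set(t.tolist()) | set(p.tolist())
    if not unknown <= set(class_labels):
        raise ValueError(f"unknown labels: {sorted(unknown - set(class_labels))}")
    k = len(class_labels)
    counts = np.zeros((k, k), dtype=int)
    for ti, pi in zip(t, p):
        counts[lut[ti], lut[pi]] += 1
    return ConfusionMatrix(counts=counts, class_labels=class_labels)


def macro_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Macro precision/recall and both accuracy conventions.

    A class never predicted has undefined precision; it contributes 0 to the
    macro mean and is flagged (with a warning) rather than dropped.
    """
    counts = cm.counts
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    diag = np.diag(counts).astype(float)
    col = counts.sum(axis=0).astype(float)
    row = counts.sum(axis=1).astype(float)
    undefined = tuple(int(cm.class_labels[i]) for i in np.nonzero(col == 0)[0])
    if undefined:
        warnings.warn(
            f"classes never predicted, precision counted as 0: {undefined}",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(col > 0, diag / np.where(col > 0, col, 1), 0.0)
        rec = np.where(row > 0, diag / np.where(row > 0, row, 1), 0.0)
    return MetricsReport(
        macro_precision=float(prec.mean()),
        macro_recall=float(rec.mean()),
        accuracy=float(diag.sum() / cm.total),
        mean_per_class_accuracy=float(rec.mean()),
        per_class_precision={int(c): float(v) for c, v in zip(cm.class_labels, prec)},
        per_class_recall={int(c): float(v) for c, v in zip(cm.class_labels, rec)},
        confusion=cm,
        undefined_precision_classes=undefined,
    )


def confusion_to_csv(cm: ConfusionMatrix, path, normalized: bool = False) -> None:
    """Write the count grid (or its row-normalised display form) as CSV."""
    import pandas as pd

    data = cm.row_normalized() if normalized else cm.counts
    names = [CLASS_NAMES.get(c, str(c)) for c in cm.class_labels]
    pd.DataFrame(data, index=names, columns=names).to_csv(path, index_label="true\\pred")


def plot_confusion(cm: ConfusionMatrix, path) -> None:
    """Row-normalised heatmap (diagonal = per-class recognition rate).

    Requires matplotlib (optional dependency).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rn = cm.row_normalized()
    names = [CLASS_NAMES.get(c, str(c)) for c in cm.class_labels]
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(rn, cmap="Blues", vmin=0, vmax=1)
    ax.set_xticks(range(len(names)), names, rotation=45, ha="right")
    ax.set_yticks(range(len(names)), names)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    for i in range(rn.shape[0]):
        for j in range(rn.shape[1]):
            ax.text(j, i, f"{rn[i, j]:.2f}", ha="center", va="center",
                    color="white" if rn[i, j] > 0.5 else "black", fontsize=8)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
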
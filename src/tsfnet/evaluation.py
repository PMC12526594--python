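"""Classification metrics and reports.

Accuracy, Cohen's kappa (chance-corrected agreement ``(p0 - pe)/(1 - pe)``),
2x2 confusion matrices with per-class precision/recall, and accuracy resolved
by sliding-window right edge (seconds relative to trial onset) — the view
that exposes the hemodynamic lag between the EEG and fNIRS branches.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


def accuracy(predictions, labels) -> float:
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.size == 0:
        raise ValueError("cannot compute accuracy of an empty prediction set")
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have equal length")
    return float(np.mean(predictions == labels))


def kappa(p0: float, pe: float) -> float:
    """Cohen's kappa from observed accuracy ``p0`` and chance accuracy ``pe``.

    For balanced two-class problems the chance level shortcut is pe = 0.5.
    """
    if pe >= 1.0:
        raise ValueError("chance accuracy pe must be < 1")
    return (p0 - pe) / (1.0 - pe)


def confusion(predictions, labels) -> np.ndarray:
    """2x2 counts; rows = true class, columns = predicted class."""
    predictions = np.asarray(predictions).astype(np.int64)
    labels = np.asarray(labels).astype(np.int64)
    if not (np.isin(labels, [0, 1]).all() and np.isin(predictions, [0, 1]).all()):
        raise ValueError("confusion matrix requires binary predictions and labels")
    out = np.zeros((2, 2), dtype=np.int64)
    for t, p in zip(labels, predictions):
        out[t, p] += 1
    return out


def chance_accuracy(conf: np.ndarray) -> float:
    """Marginal-based expected agreement from a confusion matrix."""
    conf = np.asarray(conf, dtype=float)
    n = conf.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    return float((conf.sum(axis=1) * conf.sum(axis=0)).sum() / n**2)


def kappa_from_confusion(conf: np.ndarray, balanced_shortcut: bool = False) -> float:
    conf = np.asarray(conf, dtype=float)
    p0 = conf.trace() / conf.sum()
    pe = 0.5 if balanced_shortcut else chance_accuracy(conf)
    return kappa(p0, pe)


def precision_recall(conf: np.ndarray, positive: int = 1) -> tuple[float, float]:
    conf = np.asarray(conf, dtype=float)
    tp = conf[positive, positive]
    fp = conf[1 - positive, positive]
    fn = conf[positive, 1 - positive]
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    return float(precision), float(recall)


def per_window_accuracy(predictions, labels, window_right_edges) -> dict[float, float]:
    """Accuracy per sliding-window group, keyed by right edge in seconds."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    edges = np.asarray(window_right_edges)
    if edges.size != predictions.size:
        raise ValueError("window metadata missing or mismatched")
    return {float(e): accuracy(predictions[edges == e], labels[edges == e])
            for e in np.unique(edges)}


@dataclass
class EvalReport:
    """Evaluation summary for one test set."""

    accuracy: float
    kappa: float
    confusion: np.ndarray
    per_window_accuracy: dict[float, float]
    n_samples: int
    branch_accuracy: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        conf = np.asarray(self.confusion)
        if conf.sum() != self.n_samples:
            raise ValueError("confusion counts must sum to n_samples")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "accuracy": self.accuracy,
            "kappa": self.kappa,
            "confusion": np.asarray(self.confusion).tolist(),
            "per_window_accuracy": {str(k): v for k, v in self.per_window_accuracy.items()},
            "n_samples": self.n_samples,
            "branch_accuracy": self.branch_accuracy,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "EvalReport":
        text = Path(source).read_text() if isinstance(source, Path) else source
        raw = json.loads(text)
        return cls(
            accuracy=raw["accuracy"], kappa=raw["kappa"],
            confusion=np.asarray(raw["confusion"], dtype=np.int64),
            per_window_accuracy={float(k): v for k, v in raw["per_window_accuracy"].items()},
            n_samples=raw["n_samples"],
            branch_accuracy=raw.get("branch_accuracy", {}),
        )


def make_report(pred_class, labels, window_right_edges, branch_preds=None) -> EvalReport:
    conf = confusion(pred_class, labels)
    acc = accuracy(pred_class, labels)
    branch = {}
    if branch_preds:
        branch = {name: accuracy(p, labels) for name, p in branch_preds.items()}
    return EvalReport(
        accuracy=acc,
        kappa=kappa_from_confusion(conf),
        confusion=conf,
        per_window_accuracy=per_window_accuracy(pred_class, labels, window_right_edges),
        n_samples=len(labels),
        branch_accuracy=branch,
    )


def plot_confusion(report: EvalReport, ax=None):
    """Confusion heatmap (counts annotated)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(3.2, 3))
    conf = np.asarray(report.confusion)
    ax.imshow(conf, cmap="Blues")
    for i in range(2):
        for j in range(2):
            ax.text(j, i, str(conf[i, j]), ha="center", va="center")
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    ax.set_xticks([0, 1])
    ax.set_yticks([0, 1])
    return ax


def plot_per_window(curves: dict[str, dict[float, float]], ax=None):
    """Accuracy vs window right edge for one or more prediction sources."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    for name, curve in curves.items():
        edges = sorted(curve)
        ax.plot(edges, [curve[e] for e in edges], marker="o", label=name)
    ax.set_xlabel("window right edge (s)")
    ax.set_ylabel("accuracy")
    ax.legend()
    return ax
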
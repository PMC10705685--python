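"""Macro-averaged classification metrics, confusion matrix and PR/ROC curves.

The four headline metrics treat the multiclass problem as n one-vs-rest
binary problems and average arithmetically over classes:

    accuracy  = mean_i (TP_i + TN_i) / N
    precision = mean_i TP_i / (TP_i + FP_i)
    recall    = mean_i TP_i / (TP_i + FN_i)
    F1        = 2 * precision * recall / (precision + recall)

with the F1 computed from the macro precision and recall (per-class F1 values
are also reported).  Because the macro binary accuracy counts true negatives
it exceeds the plain multiclass accuracy (confusion-matrix trace over total)
for more than two classes, so both are emitted.

PR/ROC curves are one-vs-rest threshold sweeps per class; the ROC area uses
trapezoidal integration, the PR area is the step-wise average precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import (
    average_precision_score,
    confusion_matrix,
    precision_recall_curve,
    roc_curve,
    auc,
)

__all__ = ["EvalReport", "ClassCurve", "compute_metrics", "pr_roc_curves"]


@dataclass
class ClassCurve:
    """One-vs-rest PR and ROC points for a single class."""

    class_index: int
    precision: np.ndarray
    recall: np.ndarray
    pr_area: float
    fpr: np.ndarray
    tpr: np.ndarray
    roc_area: float
    defined: bool = True


@dataclass
class EvalReport:
    confusion: np.ndarray
    per_class: dict[str, np.ndarray]  # TP/TN/FP/FN arrays, one entry per class
    accuracy_eq1: float
    precision_eq2: float
    recall_eq3: float
    f1_eq4: float
    plain_accuracy: float
    per_class_f1: np.ndarray
    curves: list[ClassCurve] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "confusion": self.confusion.tolist(),
            "per_class": {k: v.tolist() for k, v in self.per_class.items()},
            "accuracy_eq1": self.accuracy_eq1,
            "precision_eq2": self.precision_eq2,
            "recall_eq3": self.recall_eq3,
            "f1_eq4": self.f1_eq4,
            "plain_accuracy": self.plain_accuracy,
            "per_class_f1": self.per_class_f1.tolist(),
            "curves": [
                {
                    "class_index": c.class_index,
                    "precision": c.precision.tolist(),
                    "recall": c.recall.tolist(),
                    "pr_area": c.pr_area,
                    "fpr": c.fpr.tolist(),
                    "tpr": c.tpr.tolist(),
                    "roc_area": c.roc_area,
                    "defined": c.defined,
                }
                for c in self.curves
            ],
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, blob: str) -> "EvalReport":
        d = json.loads(blob)
        return cls(
            confusion=np.asarray(d["confusion"]),
            per_class={k: np.asarray(v) for k, v in d["per_class"].items()},
            accuracy_eq1=d["accuracy_eq1"],
            precision_eq2=d["precision_eq2"],
            recall_eq3=d["recall_eq3"],
            f1_eq4=d["f1_eq4"],
            plain_accuracy=d["plain_accuracy"],
            per_class_f1=np.asarray(d["per_class_f1"]),
            curves=[
                ClassCurve(
                    class_index=c["class_index"],
                    precision=np.asarray(c["precision"]),
                    recall=np.asarray(c["recall"]),
                    pr_area=c["pr_area"],
                    fpr=np.asarray(c["fpr"]),
                    tpr=np.asarray(c["tpr"]),
                    roc_area=c["roc_area"],
                    defined=c["defined"],
                )
                for c in d["curves"]
            ],
        )


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros_like(num, dtype=float)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return out


def compute_metrics(y_true, y_pred, n_classes: int) -> EvalReport:
    """Confusion matrix, one-vs-rest counts and the four macro metrics."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label sequences differ in length")
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        if y.size and (y.min() < 0 or y.max() >= n_classes):
            raise ValueError(f"{name} contains labels outside [0, {n_classes})")

    conf = confusion_matrix(y_true, y_pred, labels=np.arange(n_classes))
    total = conf.sum()
    tp = np.diag(conf).astype(float)
    fp = conf.sum(axis=0) - tp
    fn = conf.sum(axis=1) - tp
    tn = total - tp - fp - fn

    precision_i = _safe_div(tp, tp + fp)
    recall_i = _safe_div(tp, tp + fn)
    acc_eq1 = float(np.mean((tp + tn) / total)) if total else 0.0
    prec_eq2 = float(precision_i.mean())
    rec_eq3 = float(recall_i.mean())
    f1_eq4 = (
        2.0 * prec_eq2 * rec_eq3 / (prec_eq2 + rec_eq3)
        if (prec_eq2 + rec_eq3) > 0
        else 0.0
    )
    per_class_f1 = _safe_div(2 * precision_i * recall_i, precision_i + recall_i)
    plain = float(tp.sum() / total) if total else 0.0

    return EvalReport(
        confusion=conf,
        per_class={"TP": tp, "TN": tn, "FP": fp, "FN": fn},
        accuracy_eq1=acc_eq1,
        precision_eq2=prec_eq2,
        recall_eq3=rec_eq3,
        f1_eq4=float(f1_eq4),
        plain_accuracy=plain,
        per_class_f1=per_class_f1,
    )


def pr_roc_curves(y_true, scores, n_classes: int) -> list[ClassCurve]:
    """One-vs-rest PR and ROC curves with areas, one per class.

    Classes absent from ``y_true`` yield a flagged, undefined curve (area
    NaN) which callers should exclude from averages.
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (len(y_true), n_classes):
        raise ValueError("score matrix shape must be (n_samples, n_classes)")
    curves = []
    for k in range(n_classes):
        pos = y_true == k
        if not pos.any() or pos.all():
            curves.append(
                ClassCurve(
                    class_index=k,
                    precision=np.array([]),
                    recall=np.array([]),
                    pr_area=float("nan"),
                    fpr=np.array([]),
                    tpr=np.array([]),
                    roc_area=float("nan"),
                    defined=False,
                )
            )
            continue
        s = scores[:, k]
        prec, rec, _ = precision_recall_curve(pos, s)
        fpr, tpr, _ = roc_curve(pos, s)
        curves.append(
            ClassCurve(
                class_index=k,
                precision=prec,
                recall=rec,
                pr_area=float(average_precision_score(pos, s)),
                fpr=fpr,
                tpr=tpr,
                roc_area=float(auc(fpr, tpr)),
            )
        )
    return curves


def plot_curves(curves: list[ClassCurve], path: str, class_names=None) -> None:
    """Side-by-side PR and ROC panels (PNG/SVG by file extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax_pr, ax_roc) = plt.subplots(1, 2, figsize=(11, 4.5))
    for c in curves:
        if not c.defined:
            continue
        name = class_names[c.class_index] if class_names else f"class {c.class_index}"
        ax_pr.plot(c.recall, c.precision, label=f"{name} (AP={c.pr_area:.3f})")
        ax_roc.plot(c.fpr, c.tpr, label=f"{name} (AUC={c.roc_area:.3f})")
    ax_pr.set_xlabel("recall"), ax_pr.set_ylabel("precision"), ax_pr.set_title("PR")
    ax_roc.set_xlabel("FPR"), ax_roc.set_ylabel("TPR"), ax_roc.set_title("ROC")
    ax_roc.plot([0, 1], [0, 1], "k--", lw=0.8)
    for ax in (ax_pr, ax_roc):
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_confusion(report: EvalReport, path: str, class_names=None) -> None:
    """Heat-map of the confusion matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = report.confusion.shape[0]
    names = class_names or [str(i) for i in range(n)]
    fig, ax = plt.subplots(figsize=(0.6 * n + 3, 0.6 * n + 2.5))
    im = ax.imshow(report.confusion, cmap="Blues")
    for i in range(n):
        for j in range(n):
            ax.text(j, i, str(report.confusion[i, j]), ha="center", va="center",
                    fontsize=7)
    ax.set_xticks(range(n), names, rotation=90, fontsize=7)
    ax.set_yticks(range(n), names, fontsize=7)
    ax.set_xlabel("predicted"), ax.set_ylabel("true")
    fig.colorbar(im, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
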
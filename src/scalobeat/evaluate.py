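"""Confusion matrix and per-class PPV / SE / ACC / F1 with macro averages.

Metrics are one-vs-rest per class i over {N, SVEB, VEB, F}:

    PPV_i = TP_i / (TP_i + FP_i)          (positive predictive value)
    SE_i  = TP_i / (TP_i + FN_i)          (sensitivity / recall)
    ACC_i = (TP_i + TN_i) / total         (one-vs-rest accuracy)
    F1_i  = 2 PPV_i SE_i / (PPV_i + SE_i)

The overall figures are unweighted arithmetic means across the four
classes, taken over the unrounded per-class values. The overall "accuracy"
is the macro average of the one-vs-rest accuracies. A zero denominator
(a class never predicted, or absent from the truth) yields 0 with a
warning — with heavily imbalanced arrhythmia classes this path is live.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "CLASSES",
    "ConfusionMatrix",
    "ClassMetrics",
    "MetricsReport",
    "confusion",
    "per_class_metrics",
    "metrics_report",
    "macro_average",
    "render_report",
]

CLASSES = ("N", "SVEB", "VEB", "F")


@dataclass(frozen=True)
class ConfusionMatrix:
    """4x4 counts, rows = true class, columns = predicted class."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (len(CLASSES), len(CLASSES)):
            raise ValueError(f"expected a 4x4 matrix, got {counts.shape}")
        if np.any(counts < 0):
            raise ValueError("confusion counts must be non-negative")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def column_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def one_vs_rest(self, i: int) -> tuple[int, int, int, int]:
        """(TP, FP, FN, TN) for class index i."""
        tp = int(self.counts[i, i])
        fp = int(self.counts[:, i].sum()) - tp
        fn = int(self.counts[i, :].sum()) - tp
        tn = self.total - tp - fp - fn
        return tp, fp, fn, tn


def confusion(true_labels, predicted_labels) -> ConfusionMatrix:
    """Tally true-vs-predicted AAMI labels into a 4x4 matrix."""
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError(
            f"length mismatch: {len(true_labels)} true vs "
            f"{len(predicted_labels)} predicted"
        )
    index = {c: k for k, c in enumerate(CLASSES)}
    counts = np.zeros((len(CLASSES), len(CLASSES)), dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise ValueError(f"unknown label in pair ({t!r}, {p!r})")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts)


@dataclass(frozen=True)
class ClassMetrics:
    ppv: float
    se: float
    acc: float
    f1: float


def _safe_ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what} has zero denominator; reporting 0", stacklevel=3)
        return 0.0
    return num / den


def per_class_metrics(cm: ConfusionMatrix, i: int | str) -> ClassMetrics:
    """One-vs-rest PPV, SE, ACC, F1 for class ``i`` (index or name)."""
    if isinstance(i, str):
        i = CLASSES.index(i)
    tp, fp, fn, tn = cm.one_vs_rest(i)
    ppv = _safe_ratio(tp, tp + fp, f"PPV[{CLASSES[i]}]")
    se = _safe_ratio(tp, tp + fn, f"SE[{CLASSES[i]}]")
    acc = _safe_ratio(tp + tn, tp + tn + fp + fn, f"ACC[{CLASSES[i]}]")
    f1 = _safe_ratio(2 * ppv * se, ppv + se, f"F1[{CLASSES[i]}]")
    return ClassMetrics(ppv, se, acc, f1)


@dataclass(frozen=True)
class MetricsReport:
    per_class: dict[str, ClassMetrics]
    macro_ppv: float
    macro_se: float
    macro_f1: float
    macro_acc: float

    def to_json(self, cm: ConfusionMatrix | None = None) -> str:
        payload: dict = {
            "per_class": {c: asdict(m) for c, m in self.per_class.items()},
            "macro": {
                "ppv": self.macro_ppv,
                "se": self.macro_se,
                "f1": self.macro_f1,
                "acc": self.macro_acc,
            },
        }
        if cm is not None:
            payload["confusion_matrix"] = {
                "classes": list(CLASSES),
                "counts": cm.counts.tolist(),
            }
        return json.dumps(payload, indent=2)


def macro_average(reports: dict[str, ClassMetrics]) -> tuple[float, float, float, float]:
    """Unweighted means of (PPV, SE, F1, ACC) across the four classes.

    Averages use the unrounded per-class values; rounding happens only at
    display time.
    """
    missing = set(CLASSES) - set(reports)
    if missing:
        raise ValueError(f"missing classes in report: {sorted(missing)}")
    ppv = float(np.mean([reports[c].ppv for c in CLASSES]))
    se = float(np.mean([reports[c].se for c in CLASSES]))
    f1 = float(np.mean([reports[c].f1 for c in CLASSES]))
    acc = float(np.mean([reports[c].acc for c in CLASSES]))
    return ppv, se, f1, acc


def metrics_report(cm: ConfusionMatrix) -> MetricsReport:
    per_class = {c: per_class_metrics(cm, k) for k, c in enumerate(CLASSES)}
    ppv, se, f1, acc = macro_average(per_class)
    return MetricsReport(per_class, ppv, se, f1, acc)


def render_report(cm: ConfusionMatrix, report: MetricsReport | None = None) -> str:
    """Text rendering: confusion matrix plus the per-class metric table."""
    report = report or metrics_report(cm)
    lines = ["Confusion matrix (rows = true, columns = predicted)"]
    header = f"{'':>6}" + "".join(f"{c:>8}" for c in CLASSES) + f"{'Total':>8}"
    lines.append(header)
    for k, c in enumerate(CLASSES):
        row = cm.counts[k]
        lines.append(
            f"{c:>6}" + "".join(f"{v:>8}" for v in row) + f"{row.sum():>8}"
        )
    col = cm.column_totals()
    lines.append(
        f"{'Total':>6}" + "".join(f"{v:>8}" for v in col) + f"{cm.total:>8}"
    )
    lines.append("")
    lines.append(f"{'Class':>6}{'PPV':>9}{'SE':>9}{'F1':>9}{'ACC':>9}")
    for c in CLASSES:
        m = report.per_class[c]
        lines.append(
            f"{c:>6}{m.ppv:>8.2%}{m.se:>8.2%}{m.f1:>8.2%}{m.acc:>8.2%}"
        )
    lines.append(
        f"{'Avg':>6}{report.macro_ppv:>8.2%}{report.macro_se:>8.2%}"
        f"{report.macro_f1:>8.2%}{report.macro_acc:>8.2%}"
    )
    return "\n".join(lines)
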
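"""Confusion-count bookkeeping and binary-classification skill scores.

The detector evaluation treats a "use" episode as the positive class and
summarises a run with true/false positive rates, precision, recall, the F1
score (harmonic mean of precision and recall), the Matthews correlation
coefficient, and the trapezoidal area under the ROC curve.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.tp + self.fp + self.tn + self.fn < 1:
            raise ValueError("confusion counts must contain at least one sample")


@dataclass(frozen=True)
class MetricsReport:
    tpr: float
    fpr: float
    precision: float
    recall: float
    f1: float
    mcc: float
    roc_area: float | None = None
    degenerate: tuple[str, ...] = ()

    def rounded(self, ndigits: int = 2) -> dict:
        """Report rounded the way results tables print (2 d.p. by default)."""
        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            out[f.name] = round(v, ndigits) if isinstance(v, float) else v
        return out

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["degenerate"] = list(self.degenerate)
        return d


def _ratio(num: float, den: float, name: str, degenerate: list[str]) -> float:
    """Zero denominators return the 0 sentinel and flag the metric."""
    if den == 0:
        degenerate.append(name)
        return 0.0
    return num / den


def compute_metrics(c: ConfusionCounts, roc_area: float | None = None) -> MetricsReport:
    """Skill scores from confusion counts.

    precision = TP/(TP+FP); recall = TPR = TP/(TP+FN); FPR = FP/(FP+TN);
    F1 = 2PR/(P+R); MCC = (TP*TN - FP*FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    Any zero denominator yields 0 with the metric named in ``degenerate``.
    """
    degenerate: list[str] = []
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    precision = _ratio(tp, tp + fp, "precision", degenerate)
    recall = _ratio(tp, tp + fn, "recall", degenerate)
    fpr = _ratio(fp, fp + tn, "fpr", degenerate)
    f1 = _ratio(2 * precision * recall, precision + recall, "f1", degenerate)
    mcc_den = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _ratio(tp * tn - fp * fn, mcc_den, "mcc", degenerate)
    return MetricsReport(tpr=recall, fpr=fpr, precision=precision, recall=recall,
                         f1=f1, mcc=mcc, roc_area=roc_area,
                         degenerate=tuple(degenerate))


def roc_curve(scores, labels, positive="use") -> tuple[np.ndarray, np.ndarray, float]:
    """ROC sweep over unique score thresholds with trapezoidal area.

    ``labels`` may be strings (compared against ``positive``) or booleans/ints.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    if labels.dtype.kind in ("U", "S", "O"):
        y = labels == positive
    else:
        y = labels.astype(bool)
    if y.all() or not y.any():
        raise ValueError("ROC requires both classes to be present")
    fpr, tpr, _ = _sk_roc_curve(y, scores)
    area = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, area
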
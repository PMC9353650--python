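"""Confusion-count bookkeeping and Acc/Pre/Rec/F1 for imbalanced classes.

Counts are kept one-vs-rest per class.  Precision, recall and F1 are
computed per class and macro-averaged (an unweighted mean across classes,
the appropriate summary under class imbalance); weighted averaging is
available as an option.  Accuracy is the pooled fraction of correct
predictions, which for the binary case coincides with
(TP + TN) / (TP + TN + FP + FN).

Division-by-zero cases (a class never predicted, or absent from the
truth) yield 0 with an explicit flag rather than NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ConfusionCounts", "MetricsReport", "confusion", "report",
           "evaluate"]


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest counts for a single class."""
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Accuracy plus (averaged) precision, recall and F1, as fractions."""
    accuracy: float
    precision: float
    recall: float
    f1: float
    zero_division: bool = False  # True if any component hit a 0/0 case

    def as_percent(self) -> dict[str, float]:
        return {k: round(getattr(self, k) * 100, 2)
                for k in ("accuracy", "precision", "recall", "f1")}

    def __str__(self) -> str:
        pct = self.as_percent()
        return ("Acc {accuracy:.2f}%  Pre {precision:.2f}%  "
                "Rec {recall:.2f}%  F1 {f1:.2f}%".format(**pct))


def confusion(y_true, y_pred, n_classes: int) -> list[ConfusionCounts]:
    """One-vs-rest confusion counts for each class."""
    y_true = np.asarray(y_true, dtype=np.intp)
    y_pred = np.asarray(y_pred, dtype=np.intp)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        if y.size and (y.min() < 0 or y.max() >= n_classes):
            raise ValueError(f"{name} contains labels outside [0, {n_classes})")
    out = []
    for c in range(n_classes):
        tp = int(np.sum((y_pred == c) & (y_true == c)))
        fp = int(np.sum((y_pred == c) & (y_true != c)))
        fn = int(np.sum((y_pred != c) & (y_true == c)))
        tn = int(np.sum((y_pred != c) & (y_true != c)))
        out.append(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
    return out


def _prf(c: ConfusionCounts) -> tuple[float, float, float, bool]:
    flag = False
    if c.tp + c.fp == 0:
        pre, flag = 0.0, True
    else:
        pre = c.tp / (c.tp + c.fp)
    if c.tp + c.fn == 0:
        rec, flag = 0.0, True
    else:
        rec = c.tp / (c.tp + c.fn)
    if pre + rec == 0:
        f1, flag = 0.0, True
    else:
        f1 = 2 * pre * rec / (pre + rec)
    return pre, rec, f1, flag


def report(counts: ConfusionCounts | list[ConfusionCounts],
           average: str = "macro") -> MetricsReport:
    """Metrics from confusion counts.

    A single ``ConfusionCounts`` is treated as the positive class of a
    binary problem: Acc = (TP+TN)/n and Pre/Rec/F1 are that class's own
    scores.  A per-class list yields pooled accuracy (= correct/total) and
    macro- (default) or support-weighted averages of Pre/Rec/F1.
    """
    if isinstance(counts, ConfusionCounts):
        if counts.n == 0:
            raise ValueError("no evaluated samples")
        pre, rec, f1, flag = _prf(counts)
        return MetricsReport(accuracy=(counts.tp + counts.tn) / counts.n,
                             precision=pre, recall=rec, f1=f1,
                             zero_division=flag)
    if not counts:
        raise ValueError("no evaluated samples")
    n = counts[0].n
    if n == 0:
        raise ValueError("no evaluated samples")
    per = [_prf(c) for c in counts]
    flag = any(p[3] for p in per)
    support = np.array([c.tp + c.fn for c in counts], dtype=float)
    if average == "macro":
        wts = np.ones(len(counts)) / len(counts)
    elif average == "weighted":
        wts = support / support.sum()
    else:
        raise ValueError(f"unknown average {average!r}")
    pre = float(sum(w * p[0] for w, p in zip(wts, per)))
    rec = float(sum(w * p[1] for w, p in zip(wts, per)))
    f1 = float(sum(w * p[2] for w, p in zip(wts, per)))
    acc = sum(c.tp for c in counts) / n
    return MetricsReport(accuracy=acc, precision=pre, recall=rec, f1=f1,
                         zero_division=flag)


def evaluate(y_true, y_pred, n_classes: int,
             average: str = "macro") -> MetricsReport:
    """Convenience wrapper: confusion counts + report in one call."""
    return report(confusion(y_true, y_pred, n_classes), average=average)
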
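"""Confusion-matrix metrics and rank-based ROC AUC.

Metrics follow the standard definitions: precision TP/(TP+FP), recall
TP/(TP+FN), specificity TN/(TN+FP), F1 = 2PR/(P+R) and accuracy. A metric
with a zero denominator is reported as ``None`` (an explicit undefined
marker), never silently as 0. Values are fractions internally; reports may
scale to percentages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(y_true, y_pred) -> ConfusionCounts:
    """2x2 confusion counts with positive class = 1."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred length mismatch")
    if not (np.isin(y_true, (0, 1)).all() and np.isin(y_pred, (0, 1)).all()):
        raise ValueError("labels must be in {0, 1}")
    return ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def f1_from_pr(precision: float, recall: float) -> float | None:
    """Harmonic mean 2PR/(P+R); works on fractions or percentages alike."""
    if precision is None or recall is None or precision + recall == 0:
        return None
    return 2 * precision * recall / (precision + recall)


def compute_metrics(c: ConfusionCounts) -> dict:
    """Precision, recall, specificity, F1 and accuracy as fractions.

    Undefined metrics (zero denominator) come back as ``None``.
    """
    if c.total == 0:
        raise ValueError("all confusion counts are zero")
    p = _ratio(c.tp, c.tp + c.fp)
    r = _ratio(c.tp, c.tp + c.fn)
    s = _ratio(c.tn, c.tn + c.fp)
    return {
        "precision": p,
        "recall": r,
        "specificity": s,
        "f1": f1_from_pr(p, r),
        "accuracy": (c.tp + c.tn) / c.total,
    }


def auc_roc(scores, y_true) -> float:
    """Rank-based (Mann-Whitney) ROC AUC; ties contribute 1/2."""
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true)
    if scores.shape != y_true.shape:
        raise ValueError("scores and labels length mismatch")
    n1 = int((y_true == 1).sum())
    n0 = int((y_true == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present for AUC")
    ranks = rankdata(scores)
    return float((ranks[y_true == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def accuracy_score(y_true, y_pred) -> float:
    c = confusion(y_true, y_pred)
    return (c.tp + c.tn) / c.total


def report_dict(y_true, y_pred, scores=None, percent: bool = False) -> dict:
    """Full evaluation report: counts plus metrics (optionally as %)."""
    c = confusion(y_true, y_pred)
    m = compute_metrics(c)
    if scores is not None and len(np.unique(y_true)) == 2:
        m["auc"] = auc_roc(np.asarray(scores, dtype=float), np.asarray(y_true))
    else:
        m["auc"] = None
    if percent:
        m = {k: (None if v is None else 100 * v) for k, v in m.items()}
    return {"tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn, **m}
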
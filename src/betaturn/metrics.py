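"""Residue-level evaluation.

Threshold metrics (Matthews correlation, Q_total, PPV, sensitivity,
specificity) from confusion counts, ROC/AUC by trapezoidal integration with
half-credit for score ties, threshold sweeps, and a z-test on the difference
of two AUCs using Hanley-McNeil standard errors (unpaired).

A score equal to the threshold counts as a positive call.  Metrics with a
zero denominator are returned as NaN and flagged, never silently zeroed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "confusion",
    "mcc",
    "q_total",
    "ppv",
    "sensitivity",
    "specificity",
    "roc_curve",
    "roc_auc",
    "metric_set",
    "threshold_sweep",
    "auc_difference_test",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _validate(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.size == 0:
        raise ValueError("empty score vector")
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    uniq = set(np.unique(labels).tolist())
    if not uniq <= {0, 1, True, False}:
        raise ValueError("labels must be binary")
    return scores, labels.astype(bool)


def confusion(scores, labels, threshold: float = 0.5) -> ConfusionCounts:
    """Confusion counts calling positive whenever score >= threshold."""
    scores, labels = _validate(scores, labels)
    calls = scores >= threshold
    return ConfusionCounts(
        tp=int(np.sum(calls & labels)),
        fp=int(np.sum(calls & ~labels)),
        tn=int(np.sum(~calls & ~labels)),
        fn=int(np.sum(~calls & labels)),
    )


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; NaN when a denominator factor is 0."""
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        return math.nan
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


def q_total(c: ConfusionCounts) -> float:
    """Percentage of correctly classified residues."""
    if c.total == 0:
        return math.nan
    return 100.0 * (c.tp + c.tn) / c.total


def ppv(c: ConfusionCounts) -> float:
    """Predicted positive value (precision), percent."""
    if c.tp + c.fp == 0:
        return math.nan
    return 100.0 * c.tp / (c.tp + c.fp)


def sensitivity(c: ConfusionCounts) -> float:
    """Recall: correctly predicted fraction of positives, percent."""
    if c.tp + c.fn == 0:
        return math.nan
    return 100.0 * c.tp / (c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    """Correctly predicted fraction of negatives, percent."""
    if c.tn + c.fp == 0:
        return math.nan
    return 100.0 * c.tn / (c.tn + c.fp)


def roc_curve(scores, labels) -> pd.DataFrame:
    """ROC points (false-positive rate, sensitivity) over all thresholds.

    Equal scores are grouped so ties contribute a single diagonal segment.
    """
    scores, labels = _validate(scores, labels)
    pos = int(labels.sum())
    neg = int((~labels).sum())
    if pos == 0 or neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    # cumulative counts at each distinct-score boundary
    boundaries = np.nonzero(np.diff(s))[0]
    idx = np.concatenate([boundaries, [len(s) - 1]])
    ctp = np.cumsum(y)[idx]
    cfp = np.cumsum(~y)[idx]
    tpr = np.concatenate([[0.0], ctp / pos])
    fpr = np.concatenate([[0.0], cfp / neg])
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})


def roc_auc(scores, labels) -> tuple[pd.DataFrame, float]:
    """ROC points and the trapezoidal AUC (equivalent to the normalized
    Mann-Whitney U with half credit for ties)."""
    points = roc_curve(scores, labels)
    auc = float(np.trapezoid(points["tpr"], points["fpr"]))
    return points, auc


@dataclass(frozen=True)
class MetricSet:
    """The evaluation bundle reported for one score/label set."""

    counts: ConfusionCounts
    threshold: float
    mcc: float
    q_total: float
    ppv: float
    sensitivity: float
    specificity: float
    auc: float

    @property
    def mcc_defined(self) -> bool:
        return not math.isnan(self.mcc)

    def to_row(self) -> dict:
        return {
            "threshold": self.threshold,
            "tp": self.counts.tp,
            "fp": self.counts.fp,
            "tn": self.counts.tn,
            "fn": self.counts.fn,
            "mcc": round(self.mcc, 3) if self.mcc_defined else math.nan,
            "q_total": round(self.q_total, 1),
            "ppv": round(self.ppv, 1) if not math.isnan(self.ppv) else math.nan,
            "sensitivity": round(self.sensitivity, 1),
            "specificity": round(self.specificity, 1),
            "auc": round(self.auc, 3),
        }


def metric_set(scores, labels, threshold: float = 0.5) -> MetricSet:
    """Compute the full metric bundle at a stated threshold."""
    c = confusion(scores, labels, threshold)
    _, auc = roc_auc(scores, labels)
    return MetricSet(
        counts=c,
        threshold=threshold,
        mcc=mcc(c),
        q_total=q_total(c),
        ppv=ppv(c),
        sensitivity=sensitivity(c),
        specificity=specificity(c),
        auc=auc,
    )


def threshold_sweep(scores, labels, step: float = 0.01) -> pd.DataFrame:
    """MCC and Q_total over a threshold grid 0..1 (inclusive, spacing `step`).

    The returned frame carries the argmax thresholds in ``df.attrs``
    (``"best_mcc_threshold"`` and ``"best_q_total_threshold"``; first grid
    point on ties).
    """
    scores, labels = _validate(scores, labels)
    thresholds = np.arange(0.0, 1.0 + step / 2, step)
    rows = []
    for t in thresholds:
        c = confusion(scores, labels, float(t))
        rows.append({"threshold": float(t), "mcc": mcc(c), "q_total": q_total(c)})
    df = pd.DataFrame(rows)
    mccs = df["mcc"].to_numpy()
    with np.errstate(invalid="ignore"):
        best_mcc = int(np.nanargmax(mccs))
    df.attrs["best_mcc_threshold"] = float(df["threshold"][best_mcc])
    df.attrs["best_q_total_threshold"] = float(
        df["threshold"][int(df["q_total"].idxmax())]
    )
    return df


def _hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc * auc)
        + (n_neg - 1) * (q2 - auc * auc)
    ) / (n_pos * n_neg)
    return math.sqrt(max(var, 0.0))


def auc_difference_test(scores_a, scores_b, labels) -> tuple[float, float]:
    """Two-sided z-test on AUC(a) - AUC(b), unpaired Hanley-McNeil errors.

    Returns (z, p).  Identical score vectors give z = 0, p = 1.
    """
    scores_a, lab = _validate(scores_a, labels)
    scores_b, _ = _validate(scores_b, labels)
    _, auc_a = roc_auc(scores_a, lab)
    _, auc_b = roc_auc(scores_b, lab)
    n_pos = int(lab.sum())
    n_neg = int((~lab).sum())
    diff = auc_a - auc_b
    se = math.hypot(
        _hanley_mcneil_se(auc_a, n_pos, n_neg),
        _hanley_mcneil_se(auc_b, n_pos, n_neg),
    )
    if diff == 0.0:
        return 0.0, 1.0
    if se == 0.0:
        return math.copysign(math.inf, diff), 0.0
    z = diff / se
    p = 2.0 * float(norm.sf(abs(z)))
    return z, p
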
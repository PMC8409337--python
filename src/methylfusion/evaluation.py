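"""Confusion-matrix metrics and ROC-AUC.

All threshold metrics are computed from TP/TN/FP/FN tallies:

* accuracy  = (TP + TN) / (TP + TN + FP + FN)
* sensitivity = TP / (TP + FN)        (true-positive rate)
* specificity = TN / (TN + FP)        (true-negative rate)
* F1 — two variants: the conventional 2·TP / (2·TP + FP + FN), and the
  threat-score form TP / (TP + FP + FN) (the Jaccard index over
  positive calls) that some site-prediction papers print under the
  name "F1".  Every report records which variant it used.
* MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)), with the
  usual convention MCC = 0 when any marginal factor vanishes
  (degenerate predictors occur routinely early in training).

AUC is the Mann–Whitney statistic: the probability that a uniformly
chosen positive outscores a uniformly chosen negative, ties counting
one half — identical to trapezoidal integration of the ROC curve.

A metric whose denominator is empty (e.g. sensitivity with no true
positives in the evaluated set) raises :class:`UndefinedMetricError`
rather than silently returning 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

F1_VARIANTS = ("standard", "paper_eq4")


class UndefinedMetricError(ArithmeticError):
    """The metric's denominator is empty for this confusion table."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _as_binary(vec, name: str) -> np.ndarray:
    arr = np.asarray(vec)
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 entries")
    return arr.astype(np.int64)


def confusion(labels, predictions) -> ConfusionCounts:
    """Tally TP/TN/FP/FN from binary truth and binary predictions."""
    y = _as_binary(labels, "labels")
    p = _as_binary(predictions, "predictions")
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} labels vs {p.shape} predictions")
    return ConfusionCounts(
        tp=int(((y == 1) & (p == 1)).sum()),
        tn=int(((y == 0) & (p == 0)).sum()),
        fp=int(((y == 0) & (p == 1)).sum()),
        fn=int(((y == 1) & (p == 0)).sum()),
    )


def accuracy(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise UndefinedMetricError("accuracy undefined on an empty set")
    return (c.tp + c.tn) / c.total


def sensitivity(c: ConfusionCounts) -> float:
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no positives in truth")
    return c.tp / (c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    if c.tn + c.fp == 0:
        raise UndefinedMetricError("specificity undefined: no negatives in truth")
    return c.tn / (c.tn + c.fp)


def f1(c: ConfusionCounts, variant: str = "standard") -> float:
    if variant not in F1_VARIANTS:
        raise ValueError(f"variant must be one of {F1_VARIANTS}, got {variant!r}")
    denom = c.tp + c.fp + c.fn
    if denom == 0:
        raise UndefinedMetricError("F1 undefined: no positives anywhere")
    if variant == "paper_eq4":
        return c.tp / denom
    return 2 * c.tp / (2 * c.tp + c.fp + c.fn)


def mcc(c: ConfusionCounts) -> float:
    denom2 = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    if denom2 == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom2)


def roc_auc(labels, scores) -> float:
    """Mann–Whitney AUC with average ranks for tied scores."""
    y = _as_binary(labels, "labels")
    s = np.asarray(scores, dtype=np.float64)
    if y.shape != s.shape:
        raise ValueError("labels and scores must have equal length")
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC undefined: both classes must be present")
    # average ranks (1-based), ties averaged
    order = np.argsort(s, kind="mergesort")
    ranks = np.empty(y.size, dtype=np.float64)
    sorted_scores = s[order]
    i = 0
    while i < y.size:
        j = i
        while j + 1 < y.size and sorted_scores[j + 1] == sorted_scores[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    rank_sum_pos = ranks[y == 1].sum()
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass(frozen=True)
class MetricReport:
    """One row of a results table: the six metrics plus their counts."""

    accuracy: float
    f1: float
    f1_variant_used: str
    sensitivity: float | None
    specificity: float | None
    mcc: float
    auc: float | None
    counts: ConfusionCounts

    def to_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "f1": self.f1,
            "f1_variant_used": self.f1_variant_used,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "mcc": self.mcc,
            "auc": self.auc,
            "tp": self.counts.tp,
            "tn": self.counts.tn,
            "fp": self.counts.fp,
            "fn": self.counts.fn,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MetricReport":
        return cls(
            accuracy=d["accuracy"],
            f1=d["f1"],
            f1_variant_used=d["f1_variant_used"],
            sensitivity=d["sensitivity"],
            specificity=d["specificity"],
            mcc=d["mcc"],
            auc=d["auc"],
            counts=ConfusionCounts(tp=d["tp"], tn=d["tn"], fp=d["fp"], fn=d["fn"]),
        )


def report_from_scores(labels, positive_probs, f1_variant: str = "standard") -> MetricReport:
    """Build a full metric report from continuous positive-class scores.

    Hard labels use the 0.5 probability threshold; AUC uses the
    continuous scores.  Per-class metrics that are undefined on this
    set (a single-class evaluation) are reported as ``None``, never as
    a fabricated zero.
    """
    y = _as_binary(labels, "labels")
    p = np.asarray(positive_probs, dtype=np.float64)
    hard = (p >= 0.5).astype(np.int64)
    c = confusion(y, hard)

    def _maybe(fn, *args):
        try:
            return fn(*args)
        except UndefinedMetricError:
            return None

    return MetricReport(
        accuracy=accuracy(c),
        f1=_maybe(f1, c, f1_variant),
        f1_variant_used=f1_variant,
        sensitivity=_maybe(sensitivity, c),
        specificity=_maybe(specificity, c),
        mcc=mcc(c),
        auc=_maybe(roc_auc, y, p),
        counts=c,
    )


def evaluate(model, dataset, f1_variant: str = "standard") -> MetricReport:
    """Evaluate a trained model on a labelled dataset.

    Runs eval-mode prediction (deterministic for fixed weights), builds
    the confusion table from hard labels and computes all six metrics,
    AUC from the continuous positive-class probabilities.
    """
    from .training import predict  # late import: training depends on this module

    probs, _ = predict(model, dataset.windows)
    return report_from_scores(dataset.labels, probs, f1_variant=f1_variant)
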
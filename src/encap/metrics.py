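"""Confusion-derived evaluation metrics, ranking AUC, confidence-bin and
property-stratified analyses.

The thresholded metrics (accuracy, precision, recall/sensitivity,
specificity, F1, MCC) are exact closed forms of the confusion counts; AUC
is the Mann-Whitney pair statistic (ties counted 1/2).  An MCC whose
denominator contains a zero factor is reported as 0, the convention that
keeps the statistic total on degenerate confusions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats as _sstats

from .tables import PROPERTY_CLASSES


class MetricsError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    mcc: float
    auc: float | None = None

    def as_dict(self) -> dict:
        return asdict(self)


def confusion(labels, predictions) -> ConfusionCounts:
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predictions, dtype=int)
    if y.shape != p.shape:
        raise MetricsError("labels and predictions differ in length")
    if not set(np.unique(y)) <= {0, 1} or not set(np.unique(p)) <= {0, 1}:
        raise MetricsError("labels and predictions must be binary")
    return ConfusionCounts(
        tp=int(((y == 1) & (p == 1)).sum()),
        tn=int(((y == 0) & (p == 0)).sum()),
        fp=int(((y == 0) & (p == 1)).sum()),
        fn=int(((y == 1) & (p == 0)).sum()),
    )


def mcc_from_confusion(c: ConfusionCounts) -> float:
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


def metrics_from_confusion(c: ConfusionCounts) -> MetricsReport:
    if c.total == 0:
        raise MetricsError("empty confusion table")
    prec = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    rec = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    spec = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else 0.0
    f1 = 2 * prec * rec / (prec + rec) if (prec + rec) else 0.0
    return MetricsReport(
        accuracy=(c.tp + c.tn) / c.total,
        precision=prec,
        recall=rec,
        specificity=spec,
        f1=f1,
        mcc=mcc_from_confusion(c),
    )


def auc_score(labels, probabilities) -> float:
    """Mann-Whitney AUC: fraction of positive-negative pairs ranked
    correctly, ties counted 1/2."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(probabilities, dtype=float)
    pos = s[y == 1]
    neg = s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise MetricsError("AUC undefined with a single class")
    # rank-sum formulation, O(n log n), tie-aware
    ranks = _sstats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    return (r_pos - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg))


def evaluate(labels, probabilities, threshold: float = 0.5) -> MetricsReport:
    """Full report: thresholded metrics (probability >= threshold -> 1)
    plus ranking AUC when both classes are present."""
    probs = np.asarray(probabilities, dtype=float)
    preds = (probs >= threshold).astype(int)
    rep = metrics_from_confusion(confusion(labels, preds))
    y = np.asarray(labels, dtype=int)
    if 0 < y.sum() < len(y):
        rep.auc = auc_score(labels, probs)
    return rep


@dataclass
class ConfidenceBinReport:
    edges: list[float]
    counts: list[int]
    tpr: list[float | None]  # None marks an empty bin


def confidence_vs_tpr(labels, probabilities, edges=None) -> ConfidenceBinReport:
    """Per confidence bin: the number of peptides predicted in the bin and
    the fraction of them that are true positives."""
    if edges is None:
        edges = [round(0.1 * i, 1) for i in range(11)]
    edges = list(edges)
    if edges != sorted(edges) or len(set(edges)) != len(edges):
        raise MetricsError("bin edges must be strictly increasing")
    if edges[0] != 0.0 or edges[-1] != 1.0:
        raise MetricsError("bin edges must span [0, 1]")
    y = np.asarray(labels, dtype=int)
    s = np.asarray(probabilities, dtype=float)
    counts: list[int] = []
    tpr: list[float | None] = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (s >= lo) & ((s < hi) if hi < 1.0 else (s <= hi))
        n = int(mask.sum())
        counts.append(n)
        tpr.append(float(y[mask].mean()) if n else None)
    return ConfidenceBinReport(edges, counts, tpr)


@dataclass
class PropertyBinReport:
    property: str
    edges: list[float]
    counts: list[int]
    mcc: list[float | None]


def class_ratio(sequence: str, property: str) -> float:
    """Fraction of residues belonging to the named property class.

    Classes overlap by design (E, D, R, K, H are both hydrophilic and
    charged; A, G, P, Y belong to none of the three).
    """
    members = PROPERTY_CLASSES[property]
    return sum(c in members for c in sequence) / len(sequence)


def property_stratified_mcc(
    sequences, labels, predictions, property: str, edges=None
) -> PropertyBinReport:
    """MCC computed within bins of the per-peptide property-class ratio."""
    if property not in PROPERTY_CLASSES:
        raise MetricsError(f"unknown property {property!r}")
    if edges is None:
        edges = [round(0.2 * i, 1) for i in range(6)]
    edges = list(edges)
    ratios = np.array([class_ratio(s, property) for s in sequences])
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predictions, dtype=int)
    counts: list[int] = []
    mccs: list[float | None] = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (ratios >= lo) & ((ratios < hi) if hi < edges[-1] else (ratios <= hi))
        n = int(mask.sum())
        counts.append(n)
        if n == 0:
            mccs.append(None)
        else:
            mccs.append(mcc_from_confusion(confusion(y[mask], p[mask])))
    return PropertyBinReport(property, edges, counts, mccs)
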
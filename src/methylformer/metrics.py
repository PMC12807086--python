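"""Confusion counts, classification metrics, and ROC AUC.

Accuracy = (TP + TN) / (P + N), precision = TP / (TP + FP), recall = TP / P,
F1 = 2 * precision * recall / (precision + recall).  Ratios with a zero
denominator are reported as 0 and flagged in ``MetricReport.undefined`` so
reports stay machine-readable.  AUC uses the Mann-Whitney pairwise
concordance formulation with ties counted 1/2, computed from rank sums.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, Optional

import numpy as np
from scipy.stats import rankdata


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def p(self) -> int:
        """Number of actually-positive (methylated) examples."""
        return self.tp + self.fn

    @property
    def n(self) -> int:
        """Number of actually-negative (unmethylated) examples."""
        return self.fp + self.tn

    @property
    def total(self) -> int:
        return self.p + self.n


@dataclass(frozen=True)
class MetricReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: Optional[float] = None
    undefined: FrozenSet[str] = frozenset()

    def to_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "undefined": sorted(self.undefined),
        }
        if self.auc is not None:
            d["auc"] = self.auc
        return d


def confusion(labels, calls) -> ConfusionCounts:
    """Tally the four confusion cells from 0/1 labels and 0/1 calls."""
    labels = np.asarray(labels, dtype=int)
    calls = np.asarray(calls, dtype=int)
    if labels.shape != calls.shape:
        raise ValueError(
            f"labels and calls have different lengths ({labels.size} vs {calls.size})"
        )
    tp = int(np.sum((labels == 1) & (calls == 1)))
    fp = int(np.sum((labels == 0) & (calls == 1)))
    fn = int(np.sum((labels == 1) & (calls == 0)))
    tn = int(np.sum((labels == 0) & (calls == 0)))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def metrics(c: ConfusionCounts, auc: Optional[float] = None) -> MetricReport:
    """Accuracy, precision, recall and F1 from confusion counts."""
    if c.total < 1:
        raise ValueError("metrics require at least one example")
    undefined = set()

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.add(name)
            return 0.0
        return num / den

    accuracy = (c.tp + c.tn) / c.total
    precision = ratio(c.tp, c.tp + c.fp, "precision")
    recall = ratio(c.tp, c.p, "recall")
    if precision + recall == 0.0:
        undefined.add("f1")
        f1 = 0.0
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return MetricReport(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        auc=auc,
        undefined=frozenset(undefined),
    )


def roc_auc(labels, probabilities) -> float:
    """Area under the ROC curve via the Mann-Whitney statistic.

    Equals the probability that a randomly chosen methylated example scores
    above a randomly chosen unmethylated one, ties counted 1/2.  Requires
    both classes present.
    """
    labels = np.asarray(labels, dtype=int)
    probs = np.asarray(probabilities, dtype=float)
    if labels.shape != probs.shape:
        raise ValueError("labels and probabilities have different lengths")
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(probs)  # average ranks handle ties as 1/2
    rank_sum_pos = float(ranks[labels == 1].sum())
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
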
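"""Evaluation metrics: confusion-matrix statistics, ROC/AUC, concordance.

Undefined metrics (zero denominators) are surfaced as None rather than
silently reported as 0, so per-motif tables for rare motifs stay honest.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "classification_metrics",
    "roc_auc",
    "replicate_concordance",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn == 0:
            raise ValueError("confusion counts sum to zero")


@dataclass(frozen=True)
class Metrics:
    precision: float | None
    recall: float | None
    accuracy: float
    f1: float | None


def classification_metrics(c: ConfusionCounts) -> Metrics:
    """Precision TP/(TP+FP), recall TP/(TP+FN), accuracy, and F1 (the
    harmonic mean of precision and recall).  Undefined values are None."""
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else None
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    accuracy = (c.tp + c.tn) / (c.tp + c.tn + c.fp + c.fn)
    if precision is None or recall is None or (precision + recall) == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return Metrics(precision=precision, recall=recall, accuracy=accuracy, f1=f1)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> tuple[pd.DataFrame, float]:
    """ROC points over all distinct score thresholds and trapezoidal AUC.

    The trapezoid over tie groups makes the AUC equal to the Mann-Whitney
    pairwise-comparison statistic with ties counted 1/2.

    Returns
    -------
    (points, auc)
        ``points``: DataFrame with columns threshold, fpr, tpr (descending
        thresholds, starting from the (0, 0) corner).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for ROC/AUC")
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    y = labels[order]
    # indices where the (descending) score changes: threshold boundaries
    distinct = np.flatnonzero(np.diff(s)) if len(s) > 1 else np.array([], dtype=int)
    idx = np.r_[distinct, len(s) - 1]
    tps = np.cumsum(y == 1)[idx]
    fps = np.cumsum(y == 0)[idx]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    thresholds = np.r_[np.inf, s[idx]]
    auc = float(np.trapezoid(tpr, fpr))
    points = pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})
    return points, auc


def replicate_concordance(
    call_tables: Sequence[pd.DataFrame], min_coverage: int = 50
) -> pd.DataFrame:
    """Pairwise Pearson correlation of modification rates across replicates.

    Sites enter only if they pass the coverage filter in *every* replicate
    (intersection semantics); a site filtered out of one replicate is
    excluded from all pairs.  Tables need columns transcript_id, position,
    rate, coverage.

    Returns the correlation matrix as a DataFrame indexed by replicate
    number.
    """
    if len(call_tables) < 2:
        raise ValueError("need at least two replicate call tables")
    keyed = []
    for tab in call_tables:
        t = tab[tab["coverage"] >= min_coverage]
        keyed.append(
            t.set_index(["transcript_id", "position"])["rate"]
        )
    shared = keyed[0].index
    for t in keyed[1:]:
        shared = shared.intersection(t.index)
    if len(shared) == 0:
        raise ValueError("no shared sites pass the coverage filter in all replicates")
    mat = np.column_stack([t.loc[shared].to_numpy(dtype=float) for t in keyed])
    corr = np.corrcoef(mat, rowvar=False)
    labels = [f"rep{i + 1}" for i in range(len(keyed))]
    return pd.DataFrame(corr, index=labels, columns=labels)
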
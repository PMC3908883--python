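"""Evaluation metrics: confusion counts, accuracy, sensitivity, specificity, AUC.

The positive class is +1 (recurrence) throughout, so sensitivity is recall
on recurrence and specificity is recall on non-recurrence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.metrics import roc_auc_score

logger = logging.getLogger(__name__)


@dataclass
class ConfusionSummary:
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    auc: Optional[float] = None

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _check_labels(a) -> np.ndarray:
    a = np.asarray(a)
    if not np.isin(a, (-1, 1)).all():
        raise ValueError("labels must be -1 or +1")
    return a


def confusion(pred, truth) -> ConfusionSummary:
    """Counts and ratios with +1 (recurrence) as the positive class.

    Ratios undefined because a class is absent come back as NaN with a
    warning.
    """
    pred = _check_labels(pred)
    truth = _check_labels(truth)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth must have equal length")
    tp = int(((pred == 1) & (truth == 1)).sum())
    tn = int(((pred == -1) & (truth == -1)).sum())
    fp = int(((pred == 1) & (truth == -1)).sum())
    fn = int(((pred == -1) & (truth == 1)).sum())
    total = tp + tn + fp + fn
    accuracy = (tp + tn) / total
    if tp + fn == 0:
        logger.warning("no positive samples in truth; sensitivity undefined")
        sensitivity = math.nan
    else:
        sensitivity = tp / (tp + fn)
    if tn + fp == 0:
        logger.warning("no negative samples in truth; specificity undefined")
        specificity = math.nan
    else:
        specificity = tn / (tn + fp)
    return ConfusionSummary(tp=tp, tn=tn, fp=fp, fn=fn, accuracy=accuracy,
                            sensitivity=sensitivity, specificity=specificity)


def auc(scores, truth) -> float:
    """Rank-based (Mann–Whitney) AUC of continuous scores vs ±1 truth.

    Ties count 0.5; a one-class truth vector yields NaN with a warning.
    """
    truth = _check_labels(truth)
    scores = np.asarray(scores, dtype=float)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must have equal length")
    if len(set(truth.tolist())) < 2:
        logger.warning("one-class truth; AUC undefined")
        return math.nan
    return float(roc_auc_score((truth == 1).astype(int), scores))


def evaluate(pred_labels, truth, scores=None) -> ConfusionSummary:
    """Confusion summary, optionally with AUC from continuous scores."""
    summary = confusion(pred_labels, truth)
    if scores is not None:
        summary.auc = auc(scores, truth)
    return summary


def write_metrics(summary: ConfusionSummary, path) -> None:
    with open(path, "w") as fh:
        fh.write("accuracy\tsensitivity\tspecificity\tauc\n")
        auc_s = "NA" if summary.auc is None or math.isnan(summary.auc) \
            else f"{summary.auc:.6f}"
        fh.write(f"{summary.accuracy:.6f}\t{summary.sensitivity:.6f}\t"
                 f"{summary.specificity:.6f}\t{auc_s}\n")
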
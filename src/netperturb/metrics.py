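"""Binary-classification metrics and the DeLong auROC comparison test.

auROC is computed by the Mann–Whitney pair-counting identity (ties count
0.5), auPRC by step-wise precision–recall integration (no interpolation),
and the threshold metrics (accuracy, F1, MCC) from the confusion matrix at
a fixed score cutoff, 0.5 by default.  The DeLong test compares the auROCs
of two scorers evaluated on the same instances, accounting for their
correlation via midrank placement variances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

__all__ = ["EvalReport", "evaluate", "auroc", "auprc", "delong_test"]


@dataclass
class EvalReport:
    """Evaluation summary of one score vector against binary labels."""

    auroc: float
    auprc: float
    accuracy: float
    f1: float
    mcc: float
    threshold: float
    n_pos: int
    n_neg: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _validate(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and aligned")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary (0/1)")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    return scores, labels


def auroc(scores, labels) -> float:
    """Area under the ROC curve via the rank-sum identity; tied scores
    contribute half a concordant pair."""
    scores, labels = _validate(scores, labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = rankdata(scores)
    rank_sum = ranks[labels == 1].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auprc(scores, labels) -> float:
    """Area under the precision–recall curve by step-wise integration,
    sum over thresholds of (recall step) x (precision at threshold)."""
    scores, labels = _validate(scores, labels)
    order = np.argsort(-scores, kind="stable")
    scores, labels = scores[order], labels[order]
    # group tied scores: metrics change only between distinct score values
    distinct = np.flatnonzero(np.diff(scores)) if scores.size > 1 else np.array([], int)
    cut_idx = np.concatenate([distinct, [scores.size - 1]])
    tp = np.cumsum(labels)[cut_idx].astype(float)
    n_pred = cut_idx + 1.0
    precision = tp / n_pred
    recall = tp / labels.sum()
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_recall) * precision))


def evaluate(scores, labels, threshold: float = 0.5) -> EvalReport:
    """Full evaluation report at a score cutoff (prediction is positive when
    score >= threshold).  MCC is 0 when any confusion-matrix marginal is 0."""
    scores, labels = _validate(scores, labels)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    n = tp + tn + fp + fn
    accuracy = (tp + tn) / n
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / np.sqrt(denom)
    return EvalReport(
        auroc=auroc(scores, labels),
        auprc=auprc(scores, labels),
        accuracy=float(accuracy),
        f1=float(f1),
        mcc=float(mcc),
        threshold=threshold,
        n_pos=int(labels.sum()),
        n_neg=int(labels.size - labels.sum()),
    )


def _midrank_placements(scores, labels):
    """DeLong structural components: for each positive, the fraction of
    negatives it outranks (ties half), and symmetrically for negatives."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    all_ranks = rankdata(np.concatenate([pos, neg]))
    pos_ranks = rankdata(pos)
    neg_ranks = rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n  # per-positive placements
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m  # per-negative placements
    return v10, v01


def delong_test(scores_1, scores_2, labels) -> tuple[float, float, float, float]:
    """Two-sided DeLong test for paired (same-instance) auROC difference.

    Returns ``(z, p, auroc_1, auroc_2)``; the sign of z follows
    ``auroc_1 - auroc_2``.  A degenerate variance (e.g. a scorer compared
    with itself) yields ``z = 0, p = 1``.
    """
    scores_1, labels = _validate(scores_1, labels)
    scores_2, _ = _validate(scores_2, labels)
    v10_1, v01_1 = _midrank_placements(scores_1, labels)
    v10_2, v01_2 = _midrank_placements(scores_2, labels)
    auc1 = float(v10_1.mean())
    auc2 = float(v10_2.mean())
    m, n = v10_1.size, v01_1.size
    d10 = v10_1 - v10_2
    d01 = v01_1 - v01_2
    var = 0.0
    if m > 1:
        var += d10.var(ddof=1) / m
    if n > 1:
        var += d01.var(ddof=1) / n
    if var <= 1e-16:
        if abs(auc1 - auc2) <= 1e-12:  # e.g. a scorer against itself
            return 0.0, 1.0, auc1, auc2
        # zero estimated variance with a real difference: infinitely significant
        return float(np.sign(auc1 - auc2) * np.inf), 0.0, auc1, auc2
    z = (auc1 - auc2) / np.sqrt(var)
    p = float(2 * norm.sf(abs(z)))
    return float(z), p, auc1, auc2
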
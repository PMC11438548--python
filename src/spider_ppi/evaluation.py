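"""Ranking metrics, F1 threshold selection, cross-condition generalization.

AUROC uses the rank formula with half credit for ties (the probability
that a random positive outranks a random negative).  AUPRC uses step-wise
(non-interpolated) precision-recall summation over distinct score values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata


@dataclass
class EvalReport:
    auroc: float
    auprc: float
    f1_by_threshold: dict[float, float]
    positive_rate: float


def _validate(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and equally long")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    return scores, labels


def auroc(scores, labels) -> float:
    """Probability a random positive outranks a random negative; ties count half."""
    scores, labels = _validate(scores, labels)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs at least one positive and one negative")
    ranks = rankdata(scores)  # mid-ranks handle ties with half credit
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auprc(scores, labels) -> float:
    """Area under the precision-recall curve by step-wise summation.

    Items are swept in decreasing score order, tied scores as one block;
    AP = sum over blocks of (recall gain) * (precision at the block).
    """
    scores, labels = _validate(scores, labels)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("AUPRC needs at least one positive")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    area = 0.0
    tp = fp = 0
    i = 0
    n = len(s)
    while i < n:
        j = i
        while j < n and s[j] == s[i]:
            j += 1
        tp_prev = tp
        tp += int(y[i:j].sum())
        fp += (j - i) - int(y[i:j].sum())
        precision = tp / (tp + fp)
        area += (tp - tp_prev) / n_pos * precision
        i = j
    return float(area)


def f1_score_at(scores: np.ndarray, labels: np.ndarray, threshold: float) -> float:
    pred = scores >= threshold
    tp = int((pred & (labels == 1)).sum())
    fp = int((pred & (labels == 0)).sum())
    fn = int((~pred & (labels == 1)).sum())
    if tp == 0:
        return 0.0
    return 2 * tp / (2 * tp + fp + fn)


def select_threshold(scores, labels) -> float:
    """Observed score value maximizing F1; ties go to the smallest threshold."""
    scores, labels = _validate(scores, labels)
    if labels.sum() == 0:
        raise ValueError("threshold selection needs at least one positive")
    best_t, best_f1 = None, -1.0
    for t in np.unique(scores):  # ascending, so ties keep the smallest
        f1 = f1_score_at(scores, labels, t)
        if f1 > best_f1:
            best_t, best_f1 = float(t), f1
    return best_t


def evaluate(scores, labels, thresholds=None) -> EvalReport:
    scores, labels = _validate(scores, labels)
    if thresholds is None:
        thresholds = np.unique(scores)
    return EvalReport(
        auroc=auroc(scores, labels),
        auprc=auprc(scores, labels),
        f1_by_threshold={float(t): f1_score_at(scores, labels, t) for t in thresholds},
        positive_rate=float(labels.mean()),
    )


def generalization_matrix(models: dict, datasets: dict) -> dict[tuple[str, str], float]:
    """Cross-condition AUROC table: model of one condition scored on another.

    Returns off-diagonal entries only (a model applied to its own condition
    is a cross-validation estimate, not a generalization one).  Each model
    is evaluated on its own held-out test edges of the target dataset.
    """
    out: dict[tuple[str, str], float] = {}
    for mname, model in models.items():
        for dname, ds in datasets.items():
            if mname == dname:
                continue
            edge_ids = (
                model.split.test_edges
                if model.split is not None
                else np.arange(ds.net.n_edges)
            )
            probs = model.predict_proba(ds, edge_ids)
            out[(mname, dname)] = auroc(probs, ds.labeled.labels[edge_ids])
    return out
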
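"""Unsupervised comparators: node removal, edge reweighting, co-abundance.

Node removal (NR) keeps only nodes whose genes are expressed above a
threshold and the edges among them.  Edge reweighting (ERW) multiplies each
edge weight by rw^n where n is the number of lowly/unexpressed endpoints
(default penalty rw = 0.001).  The co-abundance baseline scores a pair by
the Pearson correlation of its abundance profiles, calibrated by a
univariate logistic model against protein-complex co-membership.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from sklearn.linear_model import LogisticRegression

from .evaluation import auprc, auroc
from .features import coabundance
from .io import GeneralNetwork, canonical_edge, logger


@dataclass(frozen=True)
class ERWParams:
    rw: float = 0.001
    expression_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.rw <= 1:
            raise ValueError("rw must be in (0, 1]")


def _expr_of(expression: Mapping[str, float], node: str) -> float:
    """Missing expression is treated as unexpressed."""
    v = expression.get(node, np.nan)
    return float(v) if v is not None and np.isfinite(v) else -np.inf


def node_removal(
    net: GeneralNetwork, expression: Mapping[str, float], threshold: float
) -> GeneralNetwork:
    """Induced subgraph on the expressed nodes (expression >= threshold)."""
    keep = {n for n in net.nodes if _expr_of(expression, n) >= threshold}
    ids = net.induced_edge_ids(keep)
    edges = tuple(net.edges[i] for i in ids)
    tc = net.technique_counts[ids] if len(ids) else np.zeros((0, net.technique_counts.shape[1]), int)
    return GeneralNetwork(tuple(sorted(keep)), edges, tc)


def node_removal_scores(
    net: GeneralNetwork, expression: Mapping[str, float], threshold: float
) -> np.ndarray:
    """Per-edge 0/1 score: 1 iff the edge survives node removal."""
    keep = {n for n in net.nodes if _expr_of(expression, n) >= threshold}
    return np.array([1.0 if a in keep and b in keep else 0.0 for a, b in net.edges])


def edge_reweight(
    net: GeneralNetwork,
    expression: Mapping[str, float],
    params: ERWParams = ERWParams(),
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """ERW score per edge: w * rw^n, n = number of unexpressed endpoints."""
    w = np.ones(net.n_edges) if weights is None else np.asarray(weights, float)
    out = np.empty(net.n_edges)
    for i, (a, b) in enumerate(net.edges):
        n = int(_expr_of(expression, a) < params.expression_threshold) + int(
            _expr_of(expression, b) < params.expression_threshold
        )
        out[i] = w[i] * params.rw**n
    return out


def coabundance_baseline(
    net: GeneralNetwork,
    abundance,  # protein x sample DataFrame
    complexes: Iterable[Iterable[str]],
) -> np.ndarray:
    """Calibrated co-abundance score per candidate edge.

    The raw score is the Pearson correlation of the two proteins' abundance
    profiles.  A univariate logistic model is fit with label 1 for pairs
    co-occurring in an annotated complex, then applied to every candidate
    edge; with a degenerate label set the raw correlations are returned
    with a warning.  The monotone link preserves the correlation ranking.
    """
    raw = np.zeros(net.n_edges)
    for i, (a, b) in enumerate(net.edges):
        if a in abundance.index and b in abundance.index:
            raw[i] = coabundance(
                abundance.loc[a].to_numpy(float), abundance.loc[b].to_numpy(float)
            )
    co_member = set()
    for cx in complexes:
        members = sorted(set(cx))
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                co_member.add(canonical_edge(a, b))
    labels = np.array([1 if e in co_member else 0 for e in net.edges])
    if labels.min() == labels.max():
        logger.warning(
            "complex annotation gives no positive/negative contrast; "
            "returning raw correlations"
        )
        return raw
    clf = LogisticRegression(solver="lbfgs")
    clf.fit(raw.reshape(-1, 1), labels)
    return clf.predict_proba(raw.reshape(-1, 1))[:, 1]


def sweep_threshold(
    method: str,
    net: GeneralNetwork,
    expression: Mapping[str, float],
    labels: np.ndarray,
    thresholds: Iterable[float] | None = None,
    params: ERWParams = ERWParams(),
    edge_ids: np.ndarray | None = None,
) -> tuple[float, float]:
    """AUROC/AUPRC of NR or ERW with the expression threshold as the knob.

    Each edge is ranked by the largest threshold at which it still scores
    positively (equivalently: its score profile over the sweep), which
    yields the full ROC/PR curve these threshold-based methods admit.
    """
    if thresholds is None:
        vals = [v for v in (_expr_of(expression, n) for n in net.nodes) if np.isfinite(v)]
        thresholds = sorted(set(vals))
    thresholds = list(thresholds)
    if edge_ids is None:
        edge_ids = np.arange(net.n_edges)
    edge_ids = np.asarray(edge_ids, int)
    # Score each edge by summing its per-threshold scores: for NR this is the
    # number of thresholds the edge survives; for ERW it is a monotone
    # transform of min/paired endpoint expression.  Both rank edges exactly
    # as the swept-threshold curve does.
    agg = np.zeros(len(edge_ids))
    for t in thresholds:
        if method == "nr":
            s = node_removal_scores(net, expression, t)[edge_ids]
        elif method == "erw":
            p = ERWParams(rw=params.rw, expression_threshold=t)
            s = edge_reweight(net, expression, p)[edge_ids]
        else:
            raise ValueError(f"unknown baseline {method!r}")
        agg += s
    return auroc(agg, labels), auprc(agg, labels)
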
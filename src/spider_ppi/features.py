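"""Node- and edge-level classification features.

Node features are the condition's normalized gene-expression and
protein-abundance levels plus a cellular-localization probability vector;
edge features are the co-abundance and co-localization Pearson correlations
and the per-assay detection counts.  Missing measurements contribute a zero
feature plus a binary missingness indicator, so the model can distinguish
"not measured" from "lowly expressed".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import (
    GeneralNetwork,
    ConditionProfile,
    RunConfig,
    canonical_edge,
    logger,
)

MIN_SAMPLES_FOR_PEARSON = 3


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r with a total fallback: 0 for short or zero-variance input.

    Pairs with fewer than three shared (non-masked) observations, or with a
    constant vector on either side, get r = 0 so the feature stays defined
    and bounded for every pair.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    mask = ~(np.isnan(a) | np.isnan(b))
    a, b = a[mask], b[mask]
    if a.size < MIN_SAMPLES_FOR_PEARSON:
        return 0.0
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0.0
    # explicit formula: symmetric in (a, b) down to the last bit
    ac = a - a.mean()
    bc = b - b.mean()
    r = (ac @ bc) / np.sqrt((ac @ ac) * (bc @ bc))
    if not np.isfinite(r):
        return 0.0
    return float(np.clip(r, -1.0, 1.0))


def coabundance(a: np.ndarray, b: np.ndarray) -> float:
    """Co-abundance of two proteins: Pearson r of their sample profiles."""
    return pearson(a, b)


def colocalization(u: np.ndarray, v: np.ndarray) -> float:
    """Co-localization: Pearson r of two localization probability vectors.

    Constant vectors (including the all-zero vector of an unannotated
    protein) yield 0.  Unlike sample profiles, localization vectors are
    deterministic, so no minimum-length rule beyond Pearson's n >= 2.
    """
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    if u.size < 2 or np.ptp(u) == 0 or np.ptp(v) == 0:
        return 0.0
    uc = u - u.mean()
    vc = v - v.mean()
    r = (uc @ vc) / np.sqrt((uc @ uc) * (vc @ vc))
    return float(np.clip(r, -1.0, 1.0)) if np.isfinite(r) else 0.0


def _median_collapse(matrix: pd.DataFrame) -> pd.Series:
    return matrix.median(axis=1, skipna=True)


def _minmax(values: pd.Series) -> pd.Series:
    finite = values.dropna()
    if finite.empty:
        return values
    lo, hi = finite.min(), finite.max()
    if hi == lo:
        logger.warning("min-max normalization over constant values; mapping to 0")
        return values * 0.0
    return (values - lo) / (hi - lo)


def normalize_expression(raw: pd.DataFrame, scale: str = "tpm") -> pd.Series:
    """Per-gene expression level in [0, 1].

    TPM-scale input is log2(x+1)-transformed first; samples are collapsed by
    the median; the medians are min-max normalized across the genes of the
    condition.  Genes with no measurement stay NaN (callers decide the
    imputation, see :func:`assemble_dataset`).
    """
    if scale == "tpm":
        raw = np.log2(raw + 1.0)
    elif scale != "log":
        raise ValueError(f"unknown scale {scale!r}")
    return _minmax(_median_collapse(raw))


def normalize_abundance(raw: pd.DataFrame) -> pd.Series:
    """Per-protein abundance level in [0, 1] (median collapse, min-max)."""
    return _minmax(_median_collapse(raw))


def localization_vector(
    protein: str,
    annotations: dict[str, set[str]],
    compartments: list[str] | tuple[str, ...],
) -> np.ndarray:
    """Probability vector of the protein's cellular compartments.

    Mass is spread uniformly over the protein's annotated compartments
    (restricted to the fixed compartment list); unannotated proteins get the
    all-zero vector.
    """
    vec = np.zeros(len(compartments))
    hits = annotations.get(protein, set()).intersection(compartments)
    if hits:
        idx = {c: i for i, c in enumerate(compartments)}
        for c in hits:
            vec[idx[c]] = 1.0 / len(hits)
    return vec


@dataclass
class NodeFeatures:
    """Per-node features aligned to a node order.

    ``expression``/``abundance`` lie in [0, 1] with 0 at missing entries;
    the companion ``*_missing`` indicator is 1 where the measurement was
    absent.  ``localization`` rows are probability vectors (all-zero for
    unannotated proteins).
    """

    nodes: tuple[str, ...]
    expression: np.ndarray
    expression_missing: np.ndarray
    abundance: np.ndarray
    abundance_missing: np.ndarray
    localization: np.ndarray  # (n_nodes, n_compartments)


@dataclass
class EdgeFeatures:
    """Per-edge features aligned to a GeneralNetwork's edge order."""

    coabundance: np.ndarray
    colocalization: np.ndarray
    technique_counts: np.ndarray  # (n_edges, 11) float

    def matrix(self) -> np.ndarray:
        """Stack into the (n_edges, 13) block consumed by the classifier head.

        Technique counts are log1p-compressed: raw discovery counts are
        heavy-tailed and the scale carries little signal beyond the first
        few repeats.
        """
        return np.column_stack(
            [self.coabundance, self.colocalization, np.log1p(self.technique_counts)]
        )


@dataclass
class LabeledEdgeSet:
    """Candidate edges in canonical order with 0/1 activity labels."""

    edges: tuple[tuple[str, str], ...]
    labels: np.ndarray

    @property
    def positive_rate(self) -> float:
        return float(self.labels.mean()) if len(self.labels) else 0.0


@dataclass
class Dataset:
    """Everything the model needs for one condition."""

    net: GeneralNetwork
    condition_id: str
    node_features: NodeFeatures
    edge_features: EdgeFeatures
    labeled: LabeledEdgeSet | None
    n_gold_dropped: int = 0


def _series_to_feature(values: pd.Series, nodes: tuple[str, ...]) -> tuple[np.ndarray, np.ndarray]:
    feat = np.zeros(len(nodes))
    missing = np.ones(len(nodes))
    for i, n in enumerate(nodes):
        v = values.get(n, np.nan)
        if v is not None and np.isfinite(v):
            feat[i] = v
            missing[i] = 0.0
    return feat, missing


def assemble_dataset(
    net: GeneralNetwork,
    profile: ConditionProfile,
    annotations: dict[str, set[str]],
    config: RunConfig | None = None,
    compartments: list[str] | None = None,
    use_technique_features: bool = True,
) -> Dataset:
    """Assemble the labeled candidate-edge dataset for one condition.

    The candidate set is exactly the general network's edge set.  Gold
    edges outside that universe cannot be predicted and are dropped with a
    logged count.  With ``use_technique_features=False`` (e.g. when assay
    metadata characterizes only part of the interactions) the technique
    block is zeroed.
    """
    if net.n_edges == 0:
        raise ValueError("empty candidate edge set")
    if compartments is None:
        compartments = sorted({c for s in annotations.values() for c in s})

    expr = normalize_expression(profile.gene_expression, profile.expression_scale)
    abund = normalize_abundance(profile.protein_abundance)

    e_feat, e_miss = _series_to_feature(expr, net.nodes)
    a_feat, a_miss = _series_to_feature(abund, net.nodes)
    loc = np.array(
        [localization_vector(n, annotations, compartments) for n in net.nodes]
    )
    nf = NodeFeatures(net.nodes, e_feat, e_miss, a_feat, a_miss, loc)

    abund_raw = profile.protein_abundance
    coab = np.zeros(net.n_edges)
    coloc = np.zeros(net.n_edges)
    node_idx = net.node_index()
    for i, (a, b) in enumerate(net.edges):
        if a in abund_raw.index and b in abund_raw.index:
            coab[i] = coabundance(
                abund_raw.loc[a].to_numpy(float), abund_raw.loc[b].to_numpy(float)
            )
        coloc[i] = colocalization(loc[node_idx[a]], loc[node_idx[b]])
    tech = net.technique_counts.astype(float)
    if not use_technique_features:
        tech = np.zeros_like(tech)
    ef = EdgeFeatures(coab, coloc, tech)

    labeled = None
    n_dropped = 0
    if profile.gold_edges is not None:
        gold = {canonical_edge(a, b) for a, b in profile.gold_edges}
        in_universe = gold.intersection(net.edges)
        n_dropped = len(gold) - len(in_universe)
        if n_dropped:
            logger.warning(
                "%d gold edge(s) outside the general network dropped", n_dropped
            )
        labels = np.array([1 if e in in_universe else 0 for e in net.edges])
        labeled = LabeledEdgeSet(net.edges, labels)

    return Dataset(net, profile.condition_id, nf, ef, labeled, n_dropped)
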
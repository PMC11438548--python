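"""Condition-specific networks and their structural validation.

A trained model applied to one condition's features yields a weighted
network (per-edge activity probability over the general network's edge
set) and, by thresholding, an unweighted one.  Validation compares
network-to-network distances with tissue-ontology distances and tests
whether condition-enriched proteins gain relative degree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import mannwhitneyu, pearsonr, rankdata

from .features import Dataset
from .io import GeneralNetwork, logger

MIN_TISSUE_SET = 25


@dataclass
class ConditionNetwork:
    """Per-edge predicted probabilities plus a thresholded unweighted view."""

    condition_id: str
    edges: tuple[tuple[str, str], ...]
    probabilities: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        if len(self.probabilities) != len(self.edges):
            raise ValueError("probability vector length mismatch")

    @property
    def unweighted_edges(self) -> tuple[tuple[str, str], ...]:
        return tuple(
            e for e, p in zip(self.edges, self.probabilities) if p >= self.threshold
        )

    def degrees(self, nodes: tuple[str, ...]) -> np.ndarray:
        """Thresholded-network degree per node (0 for absent nodes)."""
        deg = dict.fromkeys(nodes, 0)
        for a, b in self.unweighted_edges:
            deg[a] += 1
            deg[b] += 1
        return np.array([deg[n] for n in nodes], float)


def build_network(
    model, dataset: Dataset, threshold: float = 0.39
) -> ConditionNetwork:
    """One forward pass over all candidate edges with the condition's features."""
    probs = model.predict_proba(dataset)
    return ConditionNetwork(dataset.condition_id, dataset.net.edges, probs, threshold)


# ---------------------------------------------------------------------------
# tissue ontology


@dataclass
class TissueOntology:
    """Rooted tree of tissue terms given as (parent, child) edges."""

    parent: dict[str, str]  # child -> parent; root absent
    root: str = field(init=False)

    def __post_init__(self) -> None:
        children = set(self.parent)
        parents = set(self.parent.values())
        roots = parents - children
        if len(roots) != 1:
            raise ValueError(f"ontology must have exactly one root, found {sorted(roots)}")
        (self.root,) = roots
        # reject cycles by walking every node to the root
        for node in children:
            seen = set()
            while node in self.parent:
                if node in seen:
                    raise ValueError("cycle in ontology")
                seen.add(node)
                node = self.parent[node]

    @staticmethod
    def from_edges(edges) -> "TissueOntology":
        parent = {}
        for p, c in edges:
            if c in parent:
                raise ValueError(f"node {c!r} has two parents")
            parent[c] = p
        return TissueOntology(parent)

    def path_to_root(self, node: str) -> list[str]:
        path = [node]
        while node in self.parent:
            node = self.parent[node]
            path.append(node)
        return path


def ontology_distance(ont: TissueOntology, a: str, b: str) -> int:
    """Sum of path lengths from the two terms to their lowest common ancestor."""
    pa = ont.path_to_root(a)
    pb = ont.path_to_root(b)
    ancestors_a = {n: i for i, n in enumerate(pa)}
    for j, n in enumerate(pb):
        if n in ancestors_a:
            return ancestors_a[n] + j
    raise ValueError(f"{a!r} and {b!r} share no ancestor")


def network_distance(na: ConditionNetwork, nb: ConditionNetwork) -> float:
    """Pearson distance 1 - r between the two probability vectors."""
    if na.edges != nb.edges:
        raise ValueError("networks must share the same edge universe")
    r = pearsonr(na.probabilities, nb.probabilities).statistic
    return float(1.0 - r)


def ontology_correlation(
    networks: dict[str, ConditionNetwork], ont: TissueOntology
) -> float:
    """Pearson r between all-pairs ontology distances and network distances."""
    names = sorted(networks)
    if len(names) < 3:
        raise ValueError("need at least 3 conditions for a defined correlation")
    od, nd = [], []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            od.append(ontology_distance(ont, a, b))
            nd.append(network_distance(networks[a], networks[b]))
    return float(pearsonr(od, nd).statistic)


# ---------------------------------------------------------------------------
# degree-percentile enrichment


def degree_percentiles(degrees: np.ndarray) -> np.ndarray:
    """Mid-rank percentile in [0, 1] of each node's degree."""
    return (rankdata(degrees) - 0.5) / len(degrees)


def degree_enrichment(
    net: ConditionNetwork,
    general: GeneralNetwork,
    tissue_proteins: set[str],
    min_set_size: int = MIN_TISSUE_SET,
) -> tuple[float, float] | None:
    """Do tissue-enriched proteins gain relative degree in the tissue network?

    Per protein, Delta = degree percentile in the thresholded condition
    network minus degree percentile in the general network; the Delta
    distributions of tissue proteins vs all others are compared with a
    two-sided Wilcoxon rank-sum test.  Returns (p_value, effect) where
    effect is the difference of median Deltas, or None for sets below the
    minimum size.
    """
    nodes = general.nodes
    in_set = np.array([n in tissue_proteins for n in nodes])
    if in_set.sum() < min_set_size:
        logger.warning(
            "tissue set of size %d below the minimum of %d; skipped",
            int(in_set.sum()),
            min_set_size,
        )
        return None
    all_deg = general.degrees()
    gen_deg = np.array([all_deg[n] for n in nodes], float)
    cond_deg = net.degrees(nodes)
    delta = degree_percentiles(cond_deg) - degree_percentiles(gen_deg)
    a, b = delta[in_set], delta[~in_set]
    if np.ptp(delta) == 0:
        return 1.0, 0.0
    res = mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.pvalue), float(np.median(a) - np.median(b))
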
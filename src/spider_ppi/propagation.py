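"""Network propagation and downstream gene prioritization.

Seed-gene scores diffuse over the degree-normalized weighted adjacency
with restart: s <- alpha * P s + (1 - alpha) * p0, where P is the
column-stochastic transition operator (W^T for row-stochastic W = D^-1 A)
and p0 is uniform over the seed set.  With alpha < 1 the iteration is a
contraction and converges to the unique fixed point
(I - alpha P)^-1 (1 - alpha) p0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .features import pearson
from .io import logger
from .networks import ConditionNetwork
from .evaluation import auroc

MIN_GENE_SET = 25


@dataclass(frozen=True)
class PropagationConfig:
    alpha: float = 0.8
    tolerance: float = 1e-8
    max_iterations: int = 10_000
    normalization: str = "stochastic"  # or "symmetric"

    def __post_init__(self) -> None:
        if not 0 <= self.alpha < 1:
            raise ValueError("alpha must be in [0, 1)")
        if self.normalization not in ("stochastic", "symmetric"):
            raise ValueError(f"unknown normalization {self.normalization!r}")


def _adjacency(net: ConditionNetwork, nodes: Sequence[str]) -> np.ndarray:
    idx = {n: i for i, n in enumerate(nodes)}
    A = np.zeros((len(nodes), len(nodes)))
    for (a, b), p in zip(net.edges, net.probabilities):
        A[idx[a], idx[b]] = p
        A[idx[b], idx[a]] = p
    return A


def _operator(A: np.ndarray, normalization: str) -> np.ndarray:
    deg = A.sum(axis=1)
    safe = np.where(deg > 0, deg, 1.0)
    if normalization == "stochastic":
        W = A / safe[:, None]  # row-stochastic D^-1 A
        return W.T  # mass-conserving transition operator
    half = 1.0 / np.sqrt(safe)
    return half[:, None] * A * half[None, :]


def propagate(
    net: ConditionNetwork,
    seed_genes: Iterable[str],
    config: PropagationConfig = PropagationConfig(),
    nodes: Sequence[str] | None = None,
) -> dict[str, float]:
    """Diffuse a uniform seed prior over the weighted network to a fixed point."""
    if nodes is None:
        nodes = sorted({n for e in net.edges for n in e})
    idx = {n: i for i, n in enumerate(nodes)}
    seeds = [s for s in seed_genes if s in idx]
    unknown = set(seed_genes) - set(seeds)
    if unknown:
        raise ValueError(f"seed genes not in network: {sorted(unknown)[:5]}")
    p0 = np.zeros(len(nodes))
    if not seeds:
        logger.warning("empty seed set; returning the zero vector")
        return dict.fromkeys(nodes, 0.0)
    p0[[idx[s] for s in seeds]] = 1.0 / len(seeds)
    P = _operator(_adjacency(net, nodes), config.normalization)
    s = p0.copy()
    for _ in range(config.max_iterations):
        s_new = config.alpha * (P @ s) + (1 - config.alpha) * p0
        if np.abs(s_new - s).max() < config.tolerance:
            s = s_new
            break
        s = s_new
    else:
        logger.warning("propagation did not converge within max_iterations")
    return {n: float(s[idx[n]]) for n in nodes}


def cv_disease_genes(
    net: ConditionNetwork,
    gene_set: Iterable[str],
    folds: int = 3,
    seed: int = 0,
    config: PropagationConfig = PropagationConfig(),
    min_set_size: int = MIN_GENE_SET,
) -> float | None:
    """Cross-validated propagation AUROC for recovering a disease gene set.

    The set is filtered to genes present in the network, split into folds;
    each fold is ranked by propagating from the remaining genes.  Seed
    genes are excluded from the evaluated ranking.  Returns the mean
    AUROC over folds, or None when the filtered set is below the minimum.
    """
    nodes = sorted({n for e in net.edges for n in e})
    node_set = set(nodes)
    genes = sorted(set(gene_set) & node_set)
    if len(genes) < min_set_size:
        logger.warning("gene set of size %d below %d; skipped", len(genes), min_set_size)
        return None
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(genes))
    fold_of = np.arange(len(genes)) % folds
    assignment = {genes[i]: fold_of[k] for k, i in enumerate(order)}
    scores = []
    for f in range(folds):
        held = {g for g, ff in assignment.items() if ff == f}
        seeds = [g for g in genes if g not in held]
        ranking = propagate(net, seeds, config, nodes=nodes)
        eval_nodes = [n for n in nodes if n not in seeds]
        y = np.array([1 if n in held else 0 for n in eval_nodes])
        s = np.array([ranking[n] for n in eval_nodes])
        scores.append(auroc(s, y))
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# per-sample networks and consensus


def sample_specific_dataset(dataset, abundance, sample_id: str, k: int = 5):
    """A copy of the dataset whose co-abundance feature is sample-specific.

    Used to build one predicted network per sample when a condition has
    many heterogeneous samples: the co-abundance of each candidate pair is
    recomputed over the sample and its k nearest neighbors (cosine
    similarity of abundance vectors); all other features are unchanged.
    """
    import copy as _copy

    from .features import EdgeFeatures

    coab = nearest_sample_coabundance(
        sample_id, abundance, k=k, pairs=dataset.net.edges
    )
    out = _copy.copy(dataset)
    out.edge_features = EdgeFeatures(
        np.array([coab.get(e, 0.0) for e in dataset.net.edges]),
        dataset.edge_features.colocalization,
        dataset.edge_features.technique_counts,
    )
    return out


def nearest_sample_coabundance(
    sample_id: str,
    abundance,  # protein x sample DataFrame
    k: int = 5,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> dict[tuple[str, str], float]:
    """Per-pair co-abundance from a sample and its k most similar samples.

    Similarity between samples is cosine similarity of their protein
    abundance vectors (missing values treated as 0 for the similarity);
    the co-abundance of a protein pair is then the Pearson correlation
    over the sample plus its k neighbors (k+1 values).
    """
    cols = list(abundance.columns)
    if sample_id not in cols:
        raise ValueError(f"unknown sample {sample_id!r}")
    X = abundance.fillna(0.0).to_numpy(float)
    idx = cols.index(sample_id)
    target = X[:, idx]
    norms = np.linalg.norm(X, axis=0)
    tnorm = np.linalg.norm(target)
    sims = {}
    for j, c in enumerate(cols):
        if c == sample_id:
            continue
        denom = norms[j] * tnorm
        sims[c] = float(X[:, j] @ target / denom) if denom > 0 else 0.0
    others = sorted(sims, key=lambda c: (-sims[c], c))
    if len(others) < k:
        logger.warning("pool has only %d other samples; using all", len(others))
    chosen = [sample_id] + others[:k]
    sub = abundance[chosen]
    vectors = {p: sub.loc[p].to_numpy(float) for p in abundance.index}
    if pairs is None:
        proteins = list(abundance.index)
        pairs = [
            (a, b) for i, a in enumerate(proteins) for b in proteins[i + 1 :]
        ]
    out = {}
    for a, b in pairs:
        if a in vectors and b in vectors:
            out[(a, b)] = pearson(vectors[a], vectors[b])
    return out


def consensus_network(sample_networks: Sequence[ConditionNetwork]) -> ConditionNetwork:
    """Edgewise mean of probabilities over the shared candidate edge set."""
    if not sample_networks:
        raise ValueError("no networks to aggregate")
    edges = sample_networks[0].edges
    for n in sample_networks[1:]:
        if n.edges != edges:
            raise ValueError("sample networks must share the same edge universe")
    probs = np.mean([n.probabilities for n in sample_networks], axis=0)
    return ConditionNetwork(
        sample_networks[0].condition_id + "_consensus",
        edges,
        probs,
        sample_networks[0].threshold,
    )


def driver_enrichment(
    ranked_genes: Sequence[str], cgc: Iterable[str], k: int, n_total: int
) -> float:
    """Fold enrichment of gold-standard driver genes in the top K:
    (n/K) / (|CGC|/N) with n the number of drivers among the K top-ranked."""
    cgc = set(cgc)
    if k <= 0 or k > n_total:
        raise ValueError("K must be in 1..N")
    if not cgc:
        raise ValueError("empty gold-standard set")
    n_hit = sum(1 for g in ranked_genes[:k] if g in cgc)
    return (n_hit / k) / (len(cgc) / n_total)


def score_drivers(
    consensus: ConditionNetwork,
    sample_mutations: Mapping[str, Iterable[str]],
    config: PropagationConfig = PropagationConfig(),
) -> list[str]:
    """Rank genes by mean propagation score over per-sample mutation seeds."""
    nodes = sorted({n for e in consensus.edges for n in e})
    node_set = set(nodes)
    total = np.zeros(len(nodes))
    idx = {n: i for i, n in enumerate(nodes)}
    n_samples = 0
    for sample, genes in sample_mutations.items():
        seeds = [g for g in set(genes) if g in node_set]
        if not seeds:
            logger.warning("sample %s has no mutated genes in the network", sample)
            continue
        scores = propagate(consensus, seeds, config, nodes=nodes)
        for g, v in scores.items():
            total[idx[g]] += v
        n_samples += 1
    if n_samples == 0:
        raise ValueError("no sample contributed any seeds")
    mean = total / n_samples
    return [nodes[i] for i in np.argsort(-mean, kind="stable")]
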
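"""Synthetic benchmark data with a planted, recoverable activity rule.

The generator emulates the statistical structure of the real inputs: a
general candidate network with per-assay detection counts, per-condition
expression and abundance matrices with replicate samples, compartment
annotations, and gold-standard condition-specific edge sets.  An edge's
planted activity score combines three ingredients:

* expression of both endpoints in the condition (dynamic, visible to the
  expression-threshold baselines),
* co-localization of the endpoints' compartment vectors (static),
* co-abundance, induced by protein modules sharing a latent sample factor
  (dynamic, visible only through the abundance replicates).

Because two of the three ingredients are invisible to node-removal and
edge-reweighting, a supervised model that uses all features can beat them
by construction.  Conditions evolve along a similarity tree, so sibling
conditions share more gold edges than distant ones.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .features import colocalization, localization_vector
from .io import (
    ConditionProfile,
    GeneralNetwork,
    N_TECHNIQUES,
    write_annotations,
    write_edge_list,
    write_matrix,
)
from .networks import TissueOntology


@dataclass(frozen=True)
class SynthConfig:
    """Defaults are the benchmark conditions used throughout the test suite."""

    n_proteins: int = 600
    n_edges: int = 5000
    n_conditions: int = 3
    n_samples: int = 5
    n_compartments: int = 63
    # contribution of (expression, co-localization, co-abundance) to the
    # planted activity score
    rule_weights: tuple[float, float, float] = (2.0, 2.0, 2.0)
    positive_rate: float = 0.15
    noise_sd: float = 0.3
    label_flip_rate: float = 0.02
    tree_correlation: float = 0.8
    module_size: int = 8
    #: fraction of candidate edges drawn within co-abundance modules —
    #: interaction networks are strongly enriched for intra-complex pairs
    module_edge_fraction: float = 0.3
    missing_rate: float = 0.02
    degree_distribution: str = "uniform"  # or "powerlaw"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.label_flip_rate < 0.5:
            raise ValueError("label_flip_rate must be in [0, 0.5)")
        if min(self.n_proteins, self.n_edges, self.n_conditions, self.n_samples) < 1:
            raise ValueError("all counts must be positive")


def _rng(cfg: SynthConfig, *tags) -> np.random.Generator:
    """Deterministic stream per (seed, purpose) tag tuple."""
    h = [cfg.seed] + [zlib.crc32(str(t).encode()) for t in tags]
    return np.random.default_rng(h)


def protein_ids(cfg: SynthConfig) -> list[str]:
    return [f"P{i:04d}" for i in range(cfg.n_proteins)]


def compartment_ids(cfg: SynthConfig) -> list[str]:
    return [f"C{i:02d}" for i in range(cfg.n_compartments)]


def condition_ids(cfg: SynthConfig) -> list[str]:
    return [f"cond{i}" for i in range(cfg.n_conditions)]


# ---------------------------------------------------------------------------
# structural pieces shared across conditions


def generate_general_network(cfg: SynthConfig) -> GeneralNetwork:
    """Random candidate graph with random assay-count vectors.

    A configurable fraction of edges is drawn within co-abundance modules,
    mirroring the enrichment of interaction networks for intra-complex
    pairs; the rest is drawn between uniformly (or power-law) sampled
    endpoint pairs.
    """
    rng = _rng(cfg, "network")
    prots = protein_ids(cfg)
    n = cfg.n_proteins
    max_edges = n * (n - 1) // 2
    if cfg.n_edges > max_edges:
        raise ValueError("more edges requested than pairs available")
    if cfg.degree_distribution == "powerlaw":
        w = 1.0 / np.arange(1, n + 1) ** 0.8
        p = w / w.sum()
    else:
        p = np.full(n, 1.0 / n)
    modules = module_assignment(cfg)
    by_module: dict[int, list[int]] = {}
    for i, prot in enumerate(prots):
        by_module.setdefault(modules[prot], []).append(i)
    module_pairs = [
        (a, b)
        for members in by_module.values()
        for k, a in enumerate(members)
        for b in members[k + 1 :]
    ]
    n_within = min(
        int(round(cfg.module_edge_fraction * cfg.n_edges)), len(module_pairs)
    )
    chosen: set[tuple[int, int]] = set()
    if n_within:
        picks = rng.choice(len(module_pairs), size=n_within, replace=False)
        chosen.update(module_pairs[i] for i in picks)
    while len(chosen) < cfg.n_edges:
        k = cfg.n_edges - len(chosen)
        a = rng.choice(n, size=2 * k, p=p)
        b = rng.choice(n, size=2 * k, p=p)
        for i, j in zip(a, b):
            if i == j:
                continue
            e = (min(i, j), max(i, j))
            chosen.add(e)
            if len(chosen) == cfg.n_edges:
                break
    edges = sorted((prots[i], prots[j]) for i, j in chosen)
    tc = rng.poisson(0.4, size=(cfg.n_edges, N_TECHNIQUES))
    # every interaction was detected at least once somewhere
    zero = tc.sum(axis=1) == 0
    tc[zero, N_TECHNIQUES - 1] = 1
    return GeneralNetwork(tuple(prots), tuple(edges), tc)


def generate_annotations(cfg: SynthConfig) -> dict[str, set[str]]:
    """1-3 compartments per protein; module members share a home compartment."""
    rng = _rng(cfg, "annotations")
    comps = compartment_ids(cfg)
    modules = module_assignment(cfg)
    n_modules = max(modules.values()) + 1
    home = rng.integers(0, cfg.n_compartments, size=n_modules)
    ann: dict[str, set[str]] = {}
    for p in protein_ids(cfg):
        k = int(rng.integers(1, 4))
        mine = set(rng.choice(cfg.n_compartments, size=k, replace=False).tolist())
        if rng.random() < 0.7:
            mine.add(int(home[modules[p]]))
        ann[p] = {comps[i] for i in mine}
    return ann


def module_assignment(cfg: SynthConfig) -> dict[str, int]:
    """Partition proteins into co-abundance modules (shared by all conditions)."""
    rng = _rng(cfg, "modules")
    prots = protein_ids(cfg)
    order = rng.permutation(len(prots))
    return {prots[i]: rank // cfg.module_size for rank, i in enumerate(order)}


def condition_tree(cfg: SynthConfig) -> TissueOntology:
    """Balanced binary similarity tree with the conditions as leaves."""
    leaves = condition_ids(cfg)
    edges: list[tuple[str, str]] = []
    counter = 0

    def build(group: list[str]) -> str:
        nonlocal counter
        if len(group) == 1:
            return group[0]
        name = f"I{counter}"
        counter += 1
        mid = len(group) // 2
        for child in (build(group[:mid]), build(group[mid:])):
            edges.append((name, child))
        return name

    root = build(leaves)
    if not edges:  # single condition: hang the leaf under a root term
        edges.append(("root", root))
    return TissueOntology.from_edges(edges)


def _condition_latents(cfg: SynthConfig) -> dict[str, np.ndarray]:
    """Per-condition latent gene-activity vectors evolved along the tree."""
    rng = _rng(cfg, "latents")
    tree = condition_tree(cfg)
    rho = cfg.tree_correlation
    values: dict[str, np.ndarray] = {tree.root: rng.normal(size=cfg.n_proteins)}
    children: dict[str, list[str]] = {}
    for c, p in tree.parent.items():
        children.setdefault(p, []).append(c)
    stack = [tree.root]
    while stack:
        node = stack.pop()
        for child in sorted(children.get(node, [])):
            eps = rng.normal(size=cfg.n_proteins)
            values[child] = rho * values[node] + np.sqrt(1 - rho**2) * eps
            stack.append(child)
    return {c: values[c] for c in condition_ids(cfg)}


# ---------------------------------------------------------------------------
# per-condition data


@dataclass
class ConditionTruth:
    """Planted ground truth retained for test assertions."""

    condition_id: str
    activity: np.ndarray  # per-protein expression activity in (0, 1)
    edge_scores: np.ndarray  # planted rule score per candidate edge
    rule_gold: set = field(default_factory=set)  # pre-flip gold edges


def generate_condition(
    cfg: SynthConfig,
    net: GeneralNetwork,
    condition_index: int,
    rule_weights: tuple[float, float, float] | None = None,
) -> tuple[ConditionProfile, dict[str, set[str]], ConditionTruth]:
    """One condition's profile, annotations, and planted truth.

    ``rule_weights`` overrides the config's planted rule for this condition
    only (used to create distribution-shifted transfer targets).
    """
    cid = condition_ids(cfg)[condition_index]
    rng = _rng(cfg, "condition", condition_index)
    prots = protein_ids(cfg)
    comps = compartment_ids(cfg)
    ann = generate_annotations(cfg)
    modules = module_assignment(cfg)
    z = _condition_latents(cfg)[cid]
    activity = ndtr(z)  # Phi(z) in (0, 1)

    # expression: log2-TPM around 8 * activity, replicate noise, TPM emitted
    log_expr = 8.0 * activity[:, None] + rng.normal(
        0, cfg.noise_sd, size=(cfg.n_proteins, cfg.n_samples)
    )
    tpm = np.maximum(2.0**log_expr - 1.0, 0.0)
    samples = [f"{cid}_s{j}" for j in range(cfg.n_samples)]
    expr_df = pd.DataFrame(tpm, index=prots, columns=samples)

    # abundance: base level follows activity; module members share a latent
    # per-sample factor that induces high within-module co-abundance
    n_modules = max(modules.values()) + 1
    factors = rng.normal(size=(n_modules, cfg.n_samples))
    mod_idx = np.array([modules[p] for p in prots])
    abund = (
        4.0 * activity[:, None]
        + factors[mod_idx]
        + rng.normal(0, cfg.noise_sd, size=(cfg.n_proteins, cfg.n_samples))
    )
    abund_df = pd.DataFrame(abund - abund.min() + 0.01, index=prots, columns=samples)

    # a small fraction of proteins goes unmeasured, as in real profiles
    if cfg.missing_rate > 0:
        drop_e = rng.random(cfg.n_proteins) < cfg.missing_rate
        drop_a = rng.random(cfg.n_proteins) < cfg.missing_rate
        expr_df = expr_df.loc[[p for p, d in zip(prots, drop_e) if not d]]
        abund_df = abund_df.loc[[p for p, d in zip(prots, drop_a) if not d]]

    # planted rule
    we, wl, wa = rule_weights if rule_weights is not None else cfg.rule_weights
    node_idx = {p: i for i, p in enumerate(prots)}
    loc = {p: localization_vector(p, ann, comps) for p in prots}
    scores = np.empty(net.n_edges)
    for i, (a, b) in enumerate(net.edges):
        expr_term = min(activity[node_idx[a]], activity[node_idx[b]])
        coloc_term = max(colocalization(loc[a], loc[b]), 0.0)
        coab_term = 1.0 if modules[a] == modules[b] else 0.0
        scores[i] = we * expr_term + wl * coloc_term + wa * coab_term
    cut = np.quantile(scores, 1.0 - cfg.positive_rate)
    rule_gold = {e for e, s in zip(net.edges, scores) if s > cut}
    flips = rng.random(net.n_edges) < cfg.label_flip_rate
    gold = {
        e
        for e, base, fl in zip(net.edges, scores > cut, flips)
        if bool(base) != bool(fl)
    }
    profile = ConditionProfile(cid, expr_df, abund_df, "tpm", gold)
    return profile, ann, ConditionTruth(cid, activity, scores, rule_gold)


def condition_enriched_proteins(
    net: GeneralNetwork, truth: ConditionTruth, n: int = 100
) -> set[str]:
    """The n most condition-active proteins (the tissue-enriched set analog)."""
    order = np.argsort(-truth.activity)
    return {net.nodes[i] for i in order[:n]}


# ---------------------------------------------------------------------------
# disease / driver gene sets


def _connected_module(
    edges: set,
    start_pool: list[str],
    size: int,
    rng: np.random.Generator,
    forbidden: frozenset[str] = frozenset(),
) -> list[str]:
    """Greedy BFS module of ``size`` nodes connected in the given edge set."""
    adj: dict[str, set[str]] = {}
    for a, b in edges:
        if a in forbidden or b in forbidden:
            continue
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    candidates = [n for n in start_pool if len(adj.get(n, ())) >= 2]
    if not candidates:
        candidates = [n for n in start_pool if n in adj]
    if not candidates:
        raise ValueError("gold network has no connected region to plant a module in")
    order = rng.permutation(len(candidates))
    best: list[str] = []
    for oi in order[: min(20, len(order))]:
        start = candidates[oi]
        module = [start]
        seen = {start}
        frontier = [start]
        while frontier and len(module) < size:
            nxt = sorted(
                {v for u in frontier for v in adj.get(u, ()) if v not in seen}
            )
            rng.shuffle(nxt)
            frontier = []
            for v in nxt:
                if len(module) >= size:
                    break
                module.append(v)
                seen.add(v)
                frontier.append(v)
        if len(module) > len(best):
            best = module
        if len(best) >= size:
            break
    return best


@dataclass
class DiseaseDriverSets:
    disease_genes: list[str]
    driver_module: list[str]
    cgc: list[str]  # driver module plus decoys
    sample_mutations: dict[str, list[str]]


def generate_disease_and_driver_sets(
    cfg: SynthConfig,
    net: GeneralNetwork,
    profile: ConditionProfile,
    disease_size: int = 40,
    driver_size: int = 30,
    n_decoys: int = 20,
    n_samples: int = 20,
    mutable_fraction: float = 0.5,
    mutations_per_sample: int = 3,
    passengers_per_sample: int = 20,
) -> DiseaseDriverSets:
    """Plant a disease module and a driver module in the condition's gold net.

    Disease genes form a connected module of the gold network.  The driver
    module is a second connected module; only a fixed "mutable" half of it
    ever appears in sample mutation sets (frequently vs rarely mutated
    drivers), so recovering the other half requires network inference.
    Each sample mutates a few mutable drivers plus many random passenger
    genes.  The gold-standard driver list is the full module plus random
    decoys.
    """
    if profile.gold_edges is None:
        raise ValueError("profile has no gold edges")
    rng = _rng(cfg, "disease", profile.condition_id)
    nodes = list(net.nodes)
    disease = _connected_module(profile.gold_edges, nodes, disease_size, rng)
    remaining = [n for n in nodes if n not in set(disease)]
    driver = _connected_module(
        profile.gold_edges, remaining, driver_size, rng, forbidden=frozenset(disease)
    )
    decoy_pool = [n for n in nodes if n not in set(driver)]
    decoys = rng.choice(decoy_pool, size=n_decoys, replace=False).tolist()
    n_mutable = max(2, int(round(mutable_fraction * len(driver))))
    mutable = rng.choice(driver, size=n_mutable, replace=False).tolist()
    muts: dict[str, list[str]] = {}
    for s in range(n_samples):
        k = min(mutations_per_sample, len(mutable))
        core = rng.choice(mutable, size=k, replace=False).tolist()
        passengers = rng.choice(nodes, size=passengers_per_sample, replace=False).tolist()
        muts[f"sample{s}"] = sorted(set(core + passengers))
    return DiseaseDriverSets(disease, driver, sorted(driver + decoys), muts)


# ---------------------------------------------------------------------------
# full bundle


@dataclass
class SynthBundle:
    cfg: SynthConfig
    net: GeneralNetwork
    annotations: dict[str, set[str]]
    profiles: list[ConditionProfile]
    truths: list[ConditionTruth]
    tree: TissueOntology


def generate_bundle(cfg: SynthConfig) -> SynthBundle:
    net = generate_general_network(cfg)
    profiles, truths = [], []
    ann: dict[str, set[str]] = {}
    for i in range(cfg.n_conditions):
        profile, ann, truth = generate_condition(cfg, net, i)
        profiles.append(profile)
        truths.append(truth)
    return SynthBundle(cfg, net, ann, profiles, truths, condition_tree(cfg))


def write_bundle(bundle: SynthBundle, out_dir: str | Path) -> None:
    """Emit the complete TSV bundle plus a manifest of the planted truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_edge_list(bundle.net, out / "general_network.tsv", technique_columns=True)
    write_annotations(bundle.annotations, out / "annotations.tsv")
    with open(out / "ontology.tsv", "w") as fh:
        for child, parent in sorted(bundle.tree.parent.items()):
            fh.write(f"{parent}\t{child}\n")
    manifest: dict = {"config": asdict(bundle.cfg), "conditions": {}}
    for profile, truth in zip(bundle.profiles, bundle.truths):
        cdir = out / profile.condition_id
        cdir.mkdir(exist_ok=True)
        write_matrix(profile.gene_expression, cdir / "expression.tsv")
        write_matrix(profile.protein_abundance, cdir / "abundance.tsv")
        with open(cdir / "gold_edges.tsv", "w") as fh:
            for a, b in sorted(profile.gold_edges):
                fh.write(f"{a}\t{b}\n")
        manifest["conditions"][profile.condition_id] = {
            "n_gold": len(profile.gold_edges),
            "n_rule_gold": len(truth.rule_gold),
        }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
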
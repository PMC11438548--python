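"""Tabular input/output, run configuration and deterministic seeding.

All on-disk formats are plain TSV.  Edges are always stored in canonical
(lexicographic) endpoint order so that set operations and file diffs are
deterministic regardless of input row order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("spider_ppi")

#: Fixed ordered vocabulary of interaction-detection assay categories.
#: Unknown assay names map to the final "other" category.
TECHNIQUE_CATEGORIES: tuple[str, ...] = (
    "affinity chromatography technology",
    "anti-bait coimmunoprecipitation",
    "anti-tag coimmunoprecipitation",
    "two-hybrid",
    "pull down",
    "transcriptional complementation assay",
    "affinity technology",
    "biochemical",
    "enzymatic study",
    "proximity labeling technology",
    "other",
)

N_TECHNIQUES = len(TECHNIQUE_CATEGORIES)


def canonical_edge(a: str, b: str) -> tuple[str, str]:
    """Return the unordered pair (a, b) in lexicographic order."""
    return (a, b) if a <= b else (b, a)


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Derive ``n`` independent generators from one master seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


@dataclass(frozen=True)
class GeneralNetwork:
    """Undirected candidate-interaction graph.

    The general network is the union of interactions detected in any
    condition; it defines the universe of edges for which condition-specific
    activity can be predicted.  ``technique_counts[i]`` holds, for edge
    ``edges[i]``, the number of times the interaction was discovered per
    assay category (fixed order, :data:`TECHNIQUE_CATEGORIES`).
    """

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    technique_counts: np.ndarray  # (n_edges, N_TECHNIQUES) int

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop {a!r} in GeneralNetwork")
            if a > b:
                raise ValueError(f"edge ({a!r}, {b!r}) not in canonical order")
        if self.technique_counts.shape != (len(self.edges), N_TECHNIQUES):
            raise ValueError("technique_counts shape mismatch")
        if (self.technique_counts < 0).any():
            raise ValueError("negative technique count")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.nodes)}

    def edge_index(self) -> dict[tuple[str, str], int]:
        return {e: i for i, e in enumerate(self.edges)}

    def degrees(self) -> dict[str, int]:
        deg = {n: 0 for n in self.nodes}
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg

    def induced_edge_ids(self, node_set: Iterable[str]) -> np.ndarray:
        """Indices of edges whose two endpoints both lie in ``node_set``."""
        s = set(node_set)
        return np.array(
            [i for i, (a, b) in enumerate(self.edges) if a in s and b in s],
            dtype=int,
        )

    @staticmethod
    def from_edges(
        edges: Iterable[tuple[str, str]],
        technique_counts: np.ndarray | None = None,
        extra_nodes: Iterable[str] = (),
    ) -> "GeneralNetwork":
        """Build a network from an edge iterable, canonicalizing and deduplicating.

        Counts of duplicate edges are summed; self-loops are dropped with a
        logged warning.  ``extra_nodes`` admits isolated nodes.
        """
        merged: dict[tuple[str, str], np.ndarray] = {}
        nodes: set[str] = set(extra_nodes)
        counts = (
            np.asarray(technique_counts, dtype=int)
            if technique_counts is not None
            else None
        )
        n_loops = 0
        for i, (a, b) in enumerate(edges):
            nodes.update((a, b))
            if a == b:
                n_loops += 1
                continue
            e = canonical_edge(a, b)
            row = counts[i] if counts is not None else np.zeros(N_TECHNIQUES, int)
            if e in merged:
                merged[e] = merged[e] + row
            else:
                merged[e] = row.copy()
        if n_loops:
            logger.warning("dropped %d self-loop row(s)", n_loops)
        edge_list = tuple(sorted(merged))
        tc = (
            np.array([merged[e] for e in edge_list], dtype=int)
            if edge_list
            else np.zeros((0, N_TECHNIQUES), int)
        )
        return GeneralNetwork(tuple(sorted(nodes)), edge_list, tc)


@dataclass
class ConditionProfile:
    """One condition's expression/abundance measurements and training labels.

    ``gene_expression`` and ``protein_abundance`` are row-ID x sample
    DataFrames; missing measurements are NaN (masked, never zero-filled).
    ``expression_scale`` is ``"tpm"`` (values to be log2(x+1)-transformed)
    or ``"log"`` (already on log scale).
    """

    condition_id: str
    gene_expression: pd.DataFrame
    protein_abundance: pd.DataFrame
    expression_scale: str = "tpm"
    gold_edges: set[tuple[str, str]] | None = None

    def __post_init__(self) -> None:
        if self.expression_scale not in ("tpm", "log"):
            raise ValueError(f"unknown expression scale {self.expression_scale!r}")
        for m in (self.gene_expression, self.protein_abundance):
            if m.shape[1] < 1:
                raise ValueError("profile matrix needs at least one sample")
        if self.gold_edges is not None:
            self.gold_edges = {canonical_edge(a, b) for a, b in self.gold_edges}


@dataclass
class RunConfig:
    """All tunable knobs of a run; a single seed governs every random choice."""

    embedding_size: int = 64
    learning_rate: float = 1e-3
    dropout: float = 0.3
    epochs: int = 750
    weight_decay: float = 0.01
    split_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0
    edge_threshold: float = 0.39
    alpha: float = 0.8
    rw: float = 0.001
    expression_threshold: float = 0.5

    def __post_init__(self) -> None:
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if not (0 < self.learning_rate <= 1 and 0 <= self.dropout < 1):
            raise ValueError("rates out of range")
        if not 0 <= self.alpha < 1:
            raise ValueError("alpha must be in [0, 1)")
        if not 0 < self.rw <= 1:
            raise ValueError("rw must be in (0, 1]")

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "split_fractions" in raw:
            raw["split_fractions"] = tuple(raw["split_fractions"])
        return RunConfig(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = self.__dict__.copy()
        d["split_fractions"] = list(d["split_fractions"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    def with_overrides(self, **kw) -> "RunConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# readers / writers


def read_edge_list(path: str | Path, has_technique_columns: bool = False) -> GeneralNetwork:
    """Read a two-column (plus optional 11 assay-count columns) TSV edge list.

    Duplicate rows are merged with technique counts summed; self-loop rows
    are dropped with a warning; endpoint order and row order do not matter.
    """
    edges: list[tuple[str, str]] = []
    counts: list[np.ndarray] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected at least 2 columns")
            a, b = parts[0], parts[1]
            if has_technique_columns:
                raw = parts[2:]
                if len(raw) != N_TECHNIQUES:
                    raise ValueError(
                        f"{path}:{lineno}: expected {N_TECHNIQUES} technique columns, "
                        f"got {len(raw)}"
                    )
                try:
                    vec = np.array([int(x) for x in raw])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-integer count") from exc
                if (vec < 0).any():
                    raise ValueError(f"{path}:{lineno}: negative technique count")
            else:
                vec = np.zeros(N_TECHNIQUES, int)
            edges.append((a, b))
            counts.append(vec)
    tc = np.array(counts, int) if counts else np.zeros((0, N_TECHNIQUES), int)
    return GeneralNetwork.from_edges(edges, tc)


def write_edge_list(net: GeneralNetwork, path: str | Path, technique_columns: bool = False) -> None:
    with open(path, "w") as fh:
        for i, (a, b) in enumerate(net.edges):
            row = [a, b]
            if technique_columns:
                row += [str(int(c)) for c in net.technique_counts[i]]
            fh.write("\t".join(row) + "\n")


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a row-ID x sample TSV matrix; blank/NA cells become NaN (masked)."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate row IDs: {dups}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    df.index = df.index.astype(str)
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", na_rep="NA")


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    """Read a (protein, compartment) two-column TSV into a multimap."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            out.setdefault(parts[0], set()).add(parts[1])
    return out


def write_annotations(ann: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for prot in sorted(ann):
            for comp in sorted(ann[prot]):
                fh.write(f"{prot}\t{comp}\n")


def write_condition_network(net, path: str | Path) -> None:
    """Write a ConditionNetwork as TSV (protein_a, protein_b, probability, passes)."""
    with open(path, "w") as fh:
        fh.write("protein_a\tprotein_b\tprobability\tpasses_threshold\n")
        for (a, b), p in zip(net.edges, net.probabilities):
            # unique shortest decimal that round-trips the float, >= 6 digits
            txt = np.format_float_positional(float(p), unique=True, min_digits=6)
            fh.write(f"{a}\t{b}\t{txt}\t{int(p >= net.threshold)}\n")


def read_condition_network(path: str | Path, condition_id: str = "", threshold: float | None = None):
    """Inverse of :func:`write_condition_network`."""
    from .networks import ConditionNetwork  # local import to avoid a cycle

    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    edges = tuple(
        canonical_edge(str(a), str(b)) for a, b in zip(df["protein_a"], df["protein_b"])
    )
    probs = df["probability"].to_numpy(float)
    if threshold is None:
        passing = probs[df["passes_threshold"].to_numpy(bool)]
        threshold = float(passing.min()) if passing.size else 1.1
    return ConditionNetwork(condition_id, edges, probs, threshold)
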
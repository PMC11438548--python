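"""The graph-attention pair classifier: architecture, training, transfer.

Each node feature block (expression, abundance, localization) is projected
into a joint embedding space by its own two-layer feed-forward component;
a single graph-attention layer smooths embeddings over the candidate
network; a deep-set merger (phi: one FC layer, sum pooling, rho: two FC
layers) combines the two endpoint embeddings of a queried pair into an
order-invariant edge embedding; the result, concatenated with the edge's
own features (co-abundance, co-localization, assay counts), passes through
a three-layer head ending in a sigmoid.  Sum pooling makes the score
exactly symmetric under endpoint exchange.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from itertools import product
from typing import Callable, Sequence

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .features import Dataset
from .io import GeneralNetwork, logger

#: hyperparameter grid explored during tuning
DEFAULT_GRID: dict[str, list] = {
    "embedding_size": [32, 64, 128],
    "learning_rate": [1e-3, 5e-4, 1e-4],
    "dropout": [0.2, 0.3, 0.4],
    "epochs": [500, 750, 1000],
}

FINE_TUNE_LR = 5e-4
FINE_TUNE_EPOCHS = 100

#: parameter-name prefixes of the protein-level projection blocks (frozen
#: during transfer learning)
PROJECTION_PREFIXES = ("expr_", "abund_", "loc_")


@dataclass(frozen=True)
class Hyperparameters:
    embedding_size: int = 64
    learning_rate: float = 1e-3
    dropout: float = 0.3
    epochs: int = 750
    weight_decay: float = 0.01


@dataclass
class NodeSplit:
    """Node partition into train/validation/test and the induced edge sets.

    An edge belongs to a split iff both endpoints do; edges crossing splits
    belong to none.
    """

    assignment: dict[str, str]
    train_edges: np.ndarray
    val_edges: np.ndarray
    test_edges: np.ndarray

    def nodes_in(self, *groups: str) -> set[str]:
        return {n for n, g in self.assignment.items() if g in groups}


def split_nodes(
    net: GeneralNetwork,
    fractions: Sequence[float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> NodeSplit:
    """Uniformly random 70/15/15 node partition with induced edge sets."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(net.n_nodes)
    n = net.n_nodes
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    groups = {}
    for rank, i in enumerate(order):
        if rank < n_train:
            g = "train"
        elif rank < n_train + n_val:
            g = "validation"
        else:
            g = "test"
        groups[net.nodes[i]] = g
    by_group = {
        g: {n_ for n_, gg in groups.items() if gg == g}
        for g in ("train", "validation", "test")
    }
    return NodeSplit(
        groups,
        net.induced_edge_ids(by_group["train"]),
        net.induced_edge_ids(by_group["validation"]),
        net.induced_edge_ids(by_group["test"]),
    )


# ---------------------------------------------------------------------------
# model


def _init_params(
    rng: np.random.Generator, d: int, n_compartments: int, n_edge_feats: int
) -> dict[str, Tensor]:
    p: dict[str, Tensor] = {}

    def block(prefix: str, d_in: int):
        p[f"{prefix}W1"] = ad.glorot(rng, d_in, d)
        p[f"{prefix}b1"] = ad.parameter(np.zeros(d))
        p[f"{prefix}W2"] = ad.glorot(rng, d, d)
        p[f"{prefix}b2"] = ad.parameter(np.zeros(d))

    block("expr_", 2)  # value + missingness flag
    block("abund_", 2)
    block("loc_", n_compartments)
    # graph attention
    p["gat_W"] = ad.glorot(rng, d, d)
    p["gat_a_src"] = ad.glorot(rng, d, 1)
    p["gat_a_dst"] = ad.glorot(rng, d, 1)
    # deep set
    p["phi_W"] = ad.glorot(rng, d, d)
    p["phi_b"] = ad.parameter(np.zeros(d))
    p["rho_W1"] = ad.glorot(rng, d, d)
    p["rho_b1"] = ad.parameter(np.zeros(d))
    p["rho_W2"] = ad.glorot(rng, d, d)
    p["rho_b2"] = ad.parameter(np.zeros(d))
    # head
    h2 = max(d // 2, 1)
    p["head_W1"] = ad.glorot(rng, d + n_edge_feats, d)
    p["head_b1"] = ad.parameter(np.zeros(d))
    p["head_W2"] = ad.glorot(rng, d, h2)
    p["head_b2"] = ad.parameter(np.zeros(h2))
    p["head_W3"] = ad.glorot(rng, h2, 1)
    p["head_b3"] = ad.parameter(np.zeros(1))
    return p


@dataclass
class SpiderModel:
    """Learned weights plus the hyperparameters and node split used."""

    params: dict[str, Tensor]
    hp: Hyperparameters
    split: NodeSplit | None
    n_compartments: int
    n_edge_feats: int
    loss_trace: list[float] = field(default_factory=list)

    # -- forward --------------------------------------------------------

    def _ffnn(
        self,
        x: Tensor,
        prefix: str,
        training: bool,
        rng: np.random.Generator | None,
    ) -> Tensor:
        p = self.params
        h = ad.relu(x @ p[f"{prefix}W1"] + p[f"{prefix}b1"])
        h = self._dropout(h, training, rng)
        h = ad.relu(h @ p[f"{prefix}W2"] + p[f"{prefix}b2"])
        return self._dropout(h, training, rng)

    def _dropout(self, x: Tensor, training: bool, rng) -> Tensor:
        if not training or self.hp.dropout == 0:
            return x
        keep = 1.0 - self.hp.dropout
        mask = rng.binomial(1, keep, size=x.shape) / keep
        return x * Tensor(mask)

    def node_embeddings(
        self,
        dataset: Dataset,
        message_edge_ids: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        """Project node features and smooth them with one attention layer."""
        nf = dataset.node_features
        p = self.params
        x_expr = Tensor(np.column_stack([nf.expression, nf.expression_missing]))
        x_ab = Tensor(np.column_stack([nf.abundance, nf.abundance_missing]))
        x_loc = Tensor(nf.localization)
        h = (
            self._ffnn(x_expr, "expr_", training, rng)
            + self._ffnn(x_ab, "abund_", training, rng)
            + self._ffnn(x_loc, "loc_", training, rng)
        )
        # directed message edges (both directions) plus self-loops
        n = dataset.net.n_nodes
        node_idx = dataset.net.node_index()
        pairs = [dataset.net.edges[i] for i in np.asarray(message_edge_ids, int)]
        src = np.array(
            [node_idx[a] for a, b in pairs]
            + [node_idx[b] for a, b in pairs]
            + list(range(n)),
            dtype=int,
        )
        dst = np.array(
            [node_idx[b] for a, b in pairs]
            + [node_idx[a] for a, b in pairs]
            + list(range(n)),
            dtype=int,
        )
        wh = h @ p["gat_W"]
        s_src = wh @ p["gat_a_src"]
        s_dst = wh @ p["gat_a_dst"]
        e = ad.leaky_relu(ad.gather_rows(s_src, src) + ad.gather_rows(s_dst, dst))
        alpha = ad.segment_softmax(e, dst, n)
        agg = ad.segment_sum(alpha * ad.gather_rows(wh, src), dst, n)
        return ad.elu(agg)

    def edge_logits(
        self,
        dataset: Dataset,
        edge_ids: np.ndarray,
        message_edge_ids: np.ndarray | None = None,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        """Symmetric pair logits for the queried candidate edges."""
        if message_edge_ids is None:
            message_edge_ids = np.arange(dataset.net.n_edges)
        h = self.node_embeddings(dataset, message_edge_ids, training, rng)
        node_idx = dataset.net.node_index()
        edge_ids = np.asarray(edge_ids, int)
        u = np.array([node_idx[dataset.net.edges[i][0]] for i in edge_ids])
        v = np.array([node_idx[dataset.net.edges[i][1]] for i in edge_ids])
        edge_block = dataset.edge_features.matrix()[edge_ids]
        return self.pair_logits(h, u, v, edge_block, training, rng)

    def pair_logits(
        self,
        h: Tensor,
        u: np.ndarray,
        v: np.ndarray,
        edge_block: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        """Deep-set merger and classification head for (u, v) endpoint pairs.

        phi is applied to each endpoint embedding, the outputs are summed
        (so the result is exactly invariant to exchanging u and v), rho is
        applied, and the edge's own features join before the 3-layer head.
        """
        p = self.params
        phi = ad.relu(h @ p["phi_W"] + p["phi_b"])
        pooled = ad.gather_rows(phi, u) + ad.gather_rows(phi, v)
        r = ad.relu(pooled @ p["rho_W1"] + p["rho_b1"])
        r = ad.relu(r @ p["rho_W2"] + p["rho_b2"])
        z = ad.concat([r, Tensor(edge_block)], axis=1)
        z = self._dropout(ad.relu(z @ p["head_W1"] + p["head_b1"]), training, rng)
        z = self._dropout(ad.relu(z @ p["head_W2"] + p["head_b2"]), training, rng)
        return z @ p["head_W3"] + p["head_b3"]

    def predict_proba(
        self, dataset: Dataset, edge_ids: np.ndarray | None = None
    ) -> np.ndarray:
        """Per-edge activity probability, message passing over the full graph."""
        if edge_ids is None:
            edge_ids = np.arange(dataset.net.n_edges)
        logits = self.edge_logits(dataset, edge_ids, training=False)
        return 1.0 / (1.0 + np.exp(-logits.data.ravel()))

    def copy(self) -> "SpiderModel":
        new_params = {k: ad.parameter(p.data.copy()) for k, p in self.params.items()}
        return SpiderModel(
            new_params,
            self.hp,
            self.split,
            self.n_compartments,
            self.n_edge_feats,
            list(self.loss_trace),
        )


# ---------------------------------------------------------------------------
# training


def _check_labels(labels: np.ndarray, what: str) -> None:
    if len(labels) == 0 or labels.min() == labels.max():
        raise ValueError(
            f"{what} edge set has no positive or no negative examples; "
            "try a different split seed"
        )


def _message_edges(dataset: Dataset, split: NodeSplit | None) -> np.ndarray:
    """Message-passing graph during training: induced on train+validation nodes."""
    if split is None:
        return np.arange(dataset.net.n_edges)
    return dataset.net.induced_edge_ids(split.nodes_in("train", "validation"))


def _run_epochs(
    model: SpiderModel,
    batches: list[tuple[Dataset, np.ndarray, np.ndarray, np.ndarray]],
    trainable: dict[str, Tensor],
    lr: float,
    weight_decay: float,
    epochs: int,
    rng: np.random.Generator,
) -> list[float]:
    """Full-batch Adam training over one or more (dataset, edges) pools."""
    opt = ad.Adam(trainable, lr=lr, weight_decay=weight_decay)
    total = sum(len(b[1]) for b in batches)
    trace = []
    for _ in range(epochs):
        opt.zero_grad()
        loss_val = 0.0
        for dataset, edge_ids, labels, msg_ids in batches:
            logits = model.edge_logits(
                dataset, edge_ids, message_edge_ids=msg_ids, training=True, rng=rng
            )
            loss = ad.bce_with_logits(logits.sum(axis=1), labels) * (
                len(edge_ids) / total
            )
            loss.backward()
            loss_val += float(loss.data)
        if not np.isfinite(loss_val):
            raise RuntimeError(
                f"non-finite training loss at epoch {len(trace) + 1}: {loss_val}"
            )
        opt.step()
        trace.append(loss_val)
    return trace


def train(
    dataset: Dataset,
    split: NodeSplit,
    hp: Hyperparameters = Hyperparameters(),
    seed: int = 0,
) -> SpiderModel:
    """Train on the split's induced train edges with full-batch Adam + BCE."""
    if dataset.labeled is None:
        raise ValueError("training requires a labeled dataset")
    labels = dataset.labeled.labels[split.train_edges]
    _check_labels(labels, "train")
    init_rng, drop_rng = np.random.default_rng(seed).spawn(2)
    params = _init_params(
        init_rng,
        hp.embedding_size,
        dataset.node_features.localization.shape[1],
        dataset.edge_features.matrix().shape[1],
    )
    model = SpiderModel(
        params, hp, split,
        dataset.node_features.localization.shape[1],
        dataset.edge_features.matrix().shape[1],
    )
    msg = _message_edges(dataset, split)
    model.loss_trace = _run_epochs(
        model,
        [(dataset, split.train_edges, labels, msg)],
        params,
        hp.learning_rate,
        hp.weight_decay,
        hp.epochs,
        drop_rng,
    )
    return model


def train_combined(
    datasets: list[Dataset],
    split: NodeSplit,
    hp: Hyperparameters = Hyperparameters(),
    seed: int = 0,
) -> SpiderModel:
    """One shared model over several conditions of the same protein universe.

    Each condition contributes its own features and labels; the train edge
    pools are concatenated (the loss is the BCE over the union).
    """
    if not datasets:
        raise ValueError("no datasets given")
    init_rng, drop_rng = np.random.default_rng(seed).spawn(2)
    d0 = datasets[0]
    params = _init_params(
        init_rng,
        hp.embedding_size,
        d0.node_features.localization.shape[1],
        d0.edge_features.matrix().shape[1],
    )
    model = SpiderModel(
        params, hp, split,
        d0.node_features.localization.shape[1],
        d0.edge_features.matrix().shape[1],
    )
    batches = []
    for ds in datasets:
        if ds.labeled is None:
            raise ValueError(f"dataset {ds.condition_id!r} lacks labels")
        labels = ds.labeled.labels[split.train_edges]
        _check_labels(labels, f"{ds.condition_id} train")
        batches.append((ds, split.train_edges, labels, _message_edges(ds, split)))
    model.loss_trace = _run_epochs(
        model, batches, params, hp.learning_rate, hp.weight_decay, hp.epochs, drop_rng
    )
    return model


def fine_tune(
    model: SpiderModel,
    target_dataset: Dataset,
    fraction: float,
    seed: int = 0,
    learning_rate: float = FINE_TUNE_LR,
    epochs: int = FINE_TUNE_EPOCHS,
) -> SpiderModel:
    """Transfer a trained model to a new condition.

    The protein-level projection blocks are frozen; the remaining layers
    continue training on a random ``fraction`` of the target's train edges
    at a low learning rate for a small number of epochs.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if target_dataset.labeled is None:
        raise ValueError("fine-tuning requires labels on the target")
    tuned = model.copy()
    split = model.split
    pool = (
        split.train_edges if split is not None else np.arange(target_dataset.net.n_edges)
    )
    sub_rng, drop_rng = np.random.default_rng(seed).spawn(2)
    k = max(1, int(round(fraction * len(pool))))
    chosen = np.sort(sub_rng.choice(pool, size=k, replace=False))
    labels = target_dataset.labeled.labels[chosen]
    if epochs == 0:
        return tuned
    _check_labels(labels, "fine-tuning")
    trainable = {
        n: p
        for n, p in tuned.params.items()
        if not n.startswith(PROJECTION_PREFIXES)
    }
    msg = _message_edges(target_dataset, split)
    tuned.loss_trace += _run_epochs(
        tuned,
        [(target_dataset, chosen, labels, msg)],
        trainable,
        learning_rate,
        model.hp.weight_decay,
        epochs,
        drop_rng,
    )
    return tuned


def tune(
    dataset: Dataset,
    split: NodeSplit,
    grid: dict[str, list] | None = None,
    seed: int = 0,
    eval_fn: Callable[[Hyperparameters], float] | None = None,
) -> tuple[Hyperparameters, float]:
    """Exhaustive grid search selecting the highest validation AUPRC.

    Ties are broken toward the smaller embedding size, then the lower
    learning rate.  ``eval_fn`` may replace the train-and-score step (used
    to test the selection logic in isolation).
    """
    from .evaluation import auprc

    grid = dict(DEFAULT_GRID if grid is None else grid)
    keys = ["embedding_size", "learning_rate", "dropout", "epochs"]
    combos = [
        Hyperparameters(**dict(zip(keys, values)))
        for values in product(*(grid[k] for k in keys))
    ]
    best: tuple | None = None
    for hp in combos:
        if eval_fn is not None:
            score = eval_fn(hp)
        else:
            m = train(dataset, split, hp, seed)
            probs = m.predict_proba(dataset, split.val_edges)
            score = auprc(probs, dataset.labeled.labels[split.val_edges])
        key = (-score, hp.embedding_size, hp.learning_rate)
        if best is None or key < best[0]:
            best = (key, hp, score)
        logger.info("tune %s -> AUPRC %.4f", hp, score)
    return best[1], best[2]
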
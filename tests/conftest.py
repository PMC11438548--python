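import numpy as np
import pytest

import spider_ppi as sp
from spider_ppi.synthetic import SynthConfig, generate_bundle


TINY = SynthConfig(
    n_proteins=60, n_edges=220, n_conditions=2, n_samples=5, seed=7
)


@pytest.fixture(scope="session")
def tiny_bundle():
    """Small synthetic bundle shared by fast unit tests (read-only)."""
    return generate_bundle(TINY)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_bundle):
    return sp.assemble_dataset(
        tiny_bundle.net, tiny_bundle.profiles[0], tiny_bundle.annotations
    )


@pytest.fixture(scope="session")
def tiny_split(tiny_bundle):
    return sp.split_nodes(tiny_bundle.net, seed=7)


@pytest.fixture(scope="session")
def tiny_model(tiny_bundle, tiny_dataset, tiny_split):
    """A quickly trained small model for structural tests."""
    hp = sp.Hyperparameters(embedding_size=16, epochs=120, dropout=0.2)
    return sp.train(tiny_dataset, tiny_split, hp, seed=7)


def random_scores_labels(rng, n, ties=False):
    scores = rng.integers(0, 4, size=n).astype(float) if ties else rng.normal(size=n)
    labels = rng.integers(0, 2, size=n)
    if labels.sum() == 0:
        labels[0] = 1
    if labels.sum() == n:
        labels[-1] = 0
    return scores, labels
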
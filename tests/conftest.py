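import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from mdgraph import (
    DistanceArtifacts,
    MDGraph,
    RunConfig,
    build_md_graph,
    make_separable_fixture,
)


@pytest.fixture(scope="session")
def small_table():
    """Separable two-class fixture small enough for fast unit tests."""
    return make_separable_fixture(40, 20, effect=8, seed=7)


@pytest.fixture(scope="session")
def small_graph(small_table):
    config = RunConfig(metric="cosine", perc_val=10, seed=7)
    return build_md_graph(small_table, config)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_distance_artifacts(rng, n):
    """Random valid distance matrix with its derived threshold scalars."""
    M = rng.uniform(0.05, 1.0, size=(n, n))
    D = (M + M.T) / 2
    np.fill_diagonal(D, 0.0)
    off = D[np.triu_indices(n, k=1)]
    m = float(np.median(off))
    max_val = float(off.max())
    return DistanceArtifacts(D=D, metric="euclidean", m=m, max_val=max_val,
                             t=m, delta=(max_val - m) / 5.0)


def path_graph(n_nodes, n_features, rng):
    """Path 0-1-...-n with random features; handy for receptive-field checks."""
    A = np.zeros((n_nodes, n_nodes), dtype=np.int8)
    for i in range(n_nodes - 1):
        A[i, i + 1] = A[i + 1, i] = 1
    F = rng.uniform(0.5, 2.0, size=(n_nodes, n_features))
    labels = (np.arange(n_nodes) % 2).astype(int)
    return MDGraph(
        adjacency=A,
        node_features=F,
        node_labels=labels,
        sample_ids=[f"S{i}" for i in range(n_nodes)],
        feature_names=[f"F{j}" for j in range(n_features)],
    )
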
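"""Distance matrices, neighbor caps, and MD-graph construction/refinement."""

import numpy as np
import pytest

from mdgraph import (
    DistanceArtifacts,
    RunConfig,
    build_md_graph,
    compute_distance_matrix,
    construct_edges,
    make_separable_fixture,
    neighbor_caps,
    refine_edges,
)
from mdgraph.graph import inspect_neighbors
from mdgraph.io import ConfigurationError, ValidationError

from conftest import random_distance_artifacts
from oracles import brute_force_distances, mdgraph_edges_oracle


def _edges(A):
    return {frozenset((i, j)) for i, j in zip(*np.nonzero(np.triu(A, 1)))}


class TestDistanceMatrix:
    def test_hand_arithmetic(self):
        X = np.array([[1, 2, 3], [0, 0, 0]])
        assert compute_distance_matrix(X, "manhattan").D[0, 1] == 6
        X = np.array([[3, 4], [0, 0]])
        assert compute_distance_matrix(X, "euclidean").D[0, 1] == 5

    def test_cosine_definition(self):
        X = np.array([[2.0, 0.0], [4.0, 0.0], [0.0, 1.0]])
        D = compute_distance_matrix(X, "cosine").D
        assert D[0, 1] == pytest.approx(0.0, abs=1e-12)  # parallel vectors
        assert D[0, 2] == pytest.approx(1.0)             # orthogonal vectors

    def test_cosine_zero_norm_convention(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 0.0]])
        D = compute_distance_matrix(X, "cosine").D
        assert D[0, 1] == 1.0 and D[0, 2] == 0.0 and D[0, 0] == 0.0

    @pytest.mark.parametrize("metric", ["euclidean", "manhattan", "cosine"])
    def test_matches_brute_force_loop(self, metric, rng):
        X = rng.uniform(0, 10, size=(4, 6))
        got = compute_distance_matrix(X, metric)
        np.testing.assert_allclose(got.D, brute_force_distances(X, metric), atol=1e-12)
        got.validate()

    def test_threshold_scalars(self, rng):
        X = rng.uniform(size=(6, 3))
        d = compute_distance_matrix(X, "euclidean")
        off = d.D[np.triu_indices(6, 1)]
        assert d.m == np.median(off)
        assert d.max_val == off.max()
        assert d.t == d.m
        assert d.delta == pytest.approx((d.max_val - d.m) / 5)

    def test_unknown_metric_and_nan_rejected(self):
        with pytest.raises(ConfigurationError):
            compute_distance_matrix(np.ones((3, 2)), "hamming")
        with pytest.raises(ValidationError):
            compute_distance_matrix(np.array([[1.0, np.nan], [0, 1]]), "euclidean")


class TestNeighborCaps:
    def test_balanced_exact_division(self):
        assert neighbor_caps(np.zeros(100, int), 10, False) == 10

    def test_imbalanced_cohort_caps(self):
        # 336 sick / 1023 healthy at 10% -> floor to 33 and 102
        labels = np.array([1] * 336 + [0] * 1023)
        assert neighbor_caps(labels, 10, True) == (33, 102)

    def test_floor_zero_raised_to_one(self):
        labels = np.array([1, 0, 0, 0, 0])
        assert neighbor_caps(labels, 10, True) == (1, 1)

    def test_perc_val_range(self):
        with pytest.raises(ConfigurationError):
            neighbor_caps(np.zeros(10, int), 0, False)


def _artifacts(D, t, m=None, max_val=None, delta=None):
    D = np.asarray(D, dtype=float)
    off = D[np.triu_indices(len(D), 1)]
    m = t if m is None else m
    max_val = max(float(off.max()), m) if max_val is None else max_val
    return DistanceArtifacts(D=D, metric="euclidean", m=m, max_val=max_val, t=t,
                             delta=(max_val - m) / 5 if delta is None else delta)


class TestConstructEdges:
    def test_three_node_walk_trace(self):
        # d(0,1)=0.1, d(0,2)=0.9, d(1,2)=0.2, t=0.5, tau=2
        D = [[0, 0.1, 0.9], [0.1, 0, 0.2], [0.9, 0.2, 0]]
        A, state = construct_edges(_artifacts(D, t=0.5), caps=2)
        assert _edges(A) == {frozenset((0, 1)), frozenset((1, 2))}
        # node 2's own walk accepts the pre-existing 1-2 edge -> initiated-degree 1
        assert state.counts.tolist() == [1, 2, 1]

    def test_threshold_below_all_distances_gives_empty_graph(self):
        D = [[0, 0.4, 0.5], [0.4, 0, 0.6], [0.5, 0.6, 0]]
        A, state = construct_edges(_artifacts(D, t=0.1), caps=2)
        assert not A.any()
        assert state.counts.tolist() == [0, 0, 0]

    def test_cap_one_all_within_threshold(self):
        rng = np.random.default_rng(4)
        M = rng.uniform(0.1, 0.4, size=(4, 4))
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0)
        A, state = construct_edges(_artifacts(D, t=1.0), caps=1)
        assert state.counts.tolist() == [1, 1, 1, 1]
        assert 2 <= len(_edges(A)) <= 4

    def test_adjacency_symmetric_zero_diagonal(self, rng):
        dist = random_distance_artifacts(rng, 12)
        A, _ = construct_edges(dist, caps=3)
        np.testing.assert_array_equal(A, A.T)
        assert not np.diag(A).any()

    def test_imbalanced_requires_tuple_caps(self, rng):
        dist = random_distance_artifacts(rng, 6)
        with pytest.raises(ConfigurationError):
            construct_edges(dist, caps=2, imbalanced=True)

    def test_initiated_counts_respect_class_caps(self, rng):
        dist = random_distance_artifacts(rng, 20)
        labels = (np.arange(20) < 5).astype(int)  # 5 sick, 15 healthy
        caps = (2, 6)
        A, state = construct_edges(dist, caps, labels=labels, imbalanced=True)
        assert (state.counts[labels == 1] <= 2).all()
        assert (state.counts[labels == 0] <= 6).all()


class TestRefineEdges:
    def test_one_increment_rescues_standalone_node(self):
        # node 2's nearest lies at m + delta/2: one increment suffices
        D = [[0, 0.1, 0.225], [0.1, 0, 0.45], [0.225, 0.45, 0]]
        dist = _artifacts(D, t=0.2, m=0.2, max_val=0.45)  # delta = 0.05
        A, state = construct_edges(dist, caps=1)
        assert state.counts.tolist() == [1, 1, 0]
        A, t_final = refine_edges(A, dist, state)
        assert frozenset((0, 2)) in _edges(A)
        assert t_final == pytest.approx(0.25)
        assert state.counts[2] == 1

    def test_idempotent_when_caps_already_met(self, rng):
        dist = random_distance_artifacts(rng, 10)
        dist.t = dist.max_val  # everything qualifies on the first pass
        A, state = construct_edges(dist, caps=3)
        before = A.copy()
        _, t_final = refine_edges(A, dist, state)
        np.testing.assert_array_equal(A, before)
        assert t_final == dist.max_val

    def test_infeasible_cap_raises_before_mutation(self, rng):
        dist = random_distance_artifacts(rng, 5)
        A, state = construct_edges(dist, caps=5)  # tau = N > N-1 possible neighbors
        with pytest.raises(ConfigurationError, match="cap"):
            refine_edges(A, dist, state)

    def test_no_standalone_nodes_after_refinement(self, rng):
        for trial in range(10):
            dist = random_distance_artifacts(np.random.default_rng(trial), 15)
            dist.t = dist.m / 10  # force many standalone nodes initially
            A, state = construct_edges(dist, caps=3)
            A, _ = refine_edges(A, dist, state)
            assert (A.sum(axis=1) > 0).all()
            assert (state.counts >= 3).all()


class TestOracleEquivalence:
    @pytest.mark.parametrize("imbalanced", [False, True])
    def test_construction_matches_literal_brute_force(self, imbalanced):
        """Implementation vs an independent literal walk/refine oracle on
        random 5-20-node distance matrices (spot sample; the full 200-trial
        sweep lives in the acceptance suite)."""
        rng = np.random.default_rng(99)
        for trial in range(40):
            n = int(rng.integers(5, 21))
            dist = random_distance_artifacts(rng, n)
            labels = rng.integers(0, 2, size=n)
            if imbalanced:
                caps = (int(rng.integers(1, 3)), int(rng.integers(1, 4)))
                caps_vec = [caps[0] if l == 1 else caps[1] for l in labels]
            else:
                caps = int(rng.integers(1, 4))
                caps_vec = [caps] * n
            A, state = construct_edges(dist, caps, labels=labels, imbalanced=imbalanced)
            A, t_final = refine_edges(A, dist, state)
            edges_o, counts_o, t_o = mdgraph_edges_oracle(
                dist.D, caps_vec, dist.m, dist.delta, dist.max_val
            )
            assert _edges(A) == edges_o, f"trial {trial} (n={n})"
            assert state.counts.tolist() == counts_o
            assert t_final == pytest.approx(t_o)

    def test_monotonicity_in_threshold(self):
        """Raising t (fixed caps) never removes an edge from the first-pass walk."""
        rng = np.random.default_rng(17)
        for trial in range(20):
            dist = random_distance_artifacts(rng, 12)
            lo = _artifacts(dist.D, t=dist.m)
            hi = _artifacts(dist.D, t=min(dist.m * 1.5, dist.max_val))
            A_lo, _ = construct_edges(lo, caps=4)
            A_hi, _ = construct_edges(hi, caps=4)
            assert _edges(A_lo) <= _edges(A_hi)


class TestBuildMDGraph:
    def test_homophily_on_separable_fixture(self):
        table = make_separable_fixture(50, 30, effect=8, seed=3)
        config = RunConfig(metric="cosine", perc_val=10, seed=3)
        g = build_md_graph(table, config)
        D = compute_distance_matrix(table, "cosine").D
        same = table.labels[:, None] == table.labels[None, :]
        off = ~np.eye(len(D), dtype=bool)
        assert D[same & off].mean() < D[~same].mean()
        i, j = np.nonzero(np.triu(g.adjacency, 1))
        same_label_edges = np.mean(table.labels[i] == table.labels[j])
        assert same_label_edges > 0.8

    def test_two_nodes_forced_edge(self):
        table = make_separable_fixture(10, 5, effect=2, seed=0)
        # keep only two samples, one per class
        from mdgraph import OTUTable

        t2 = OTUTable(table.sample_ids[:1] + table.sample_ids[-1:],
                      table.features[[0, -1]], table.feature_names,
                      table.labels[[0, -1]])
        g = build_md_graph(t2, RunConfig(metric="euclidean", perc_val=60, seed=0))
        assert g.adjacency[0, 1] == 1

    def test_imbalanced_config_uses_class_caps_and_metadata(self):
        table = make_separable_fixture(40, 10, effect=8, seed=1,
                                       n_sick=30, n_healthy=90)
        g = build_md_graph(table, RunConfig(metric="cosine", perc_val=10,
                                            imbalanced=True, seed=1))
        assert g.tau is None
        assert g.tau_sick == 3 and g.tau_healthy == 9
        assert g.meta["metric"] == "cosine" and g.meta["imbalanced"]

    def test_inspect_neighbors_listing(self, small_table, small_graph):
        dist = compute_distance_matrix(small_table, "cosine")
        sid = small_graph.sample_ids[0]
        info = inspect_neighbors(small_graph, [sid], dist)[sid]
        assert len(info["neighbors"]) >= 1  # refinement leaves no standalone nodes
        assert info["distances"] == sorted(info["distances"])
        assert info["same_label_fraction"] > 0.8
        with pytest.raises(KeyError):
            inspect_neighbors(small_graph, ["nope"], dist)
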
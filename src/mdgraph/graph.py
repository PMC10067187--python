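"""Metagenomic disease graph (MD-graph) construction.

Samples become nodes of an unweighted, undirected graph.  Edges join
samples whose pairwise dissimilarity is at most a distance threshold t
(initialised to the median m of the off-diagonal distances), subject to a
per-node cap on the number of neighbors a node may *initiate*: tau =
floor(perc_val * N / 100) for balanced data, or class-specific caps
tau_sick / tau_healthy computed from the class sizes when the cohort is
imbalanced (this is what keeps minority-class nodes from being swamped by
majority-class edges).  Nodes that end the first pass standalone or sparse
are rescued by raising t in five steps of delta = (max_val - m)/5, after
which t reaches the matrix maximum and every candidate qualifies.

Walk accounting: during a node's own construction walk, every accepted
candidate increments that node's initiated count, whether or not the edge
was already present from an earlier walk.  The total degree of a node may
exceed its cap because other nodes also initiate edges toward it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .io import HEALTHY, SICK, ConfigurationError, OTUTable, RunConfig, ValidationError

__all__ = [
    "DistanceArtifacts",
    "MDGraph",
    "compute_distance_matrix",
    "neighbor_caps",
    "construct_edges",
    "refine_edges",
    "build_md_graph",
    "inspect_neighbors",
]

logger = logging.getLogger(__name__)

_METRICS = {"euclidean": "euclidean", "manhattan": "cityblock", "cosine": "cosine"}


@dataclass
class DistanceArtifacts:
    """N x N dissimilarity matrix plus the derived threshold scalars."""

    D: np.ndarray
    metric: str
    m: float         # median of the off-diagonal (unordered-pair) distances
    max_val: float
    t: float         # current distance threshold, starts at m
    delta: float     # refinement step (max_val - m) / 5

    def validate(self) -> None:
        D = self.D
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValidationError("distance matrix must be square")
        if not np.all(np.isfinite(D)):
            raise ValidationError("distance matrix must be finite")
        if np.any(D < 0):
            raise ValidationError("distances must be >= 0")
        if np.any(np.diag(D) != 0):
            raise ValidationError("distance matrix diagonal must be 0")
        if not np.allclose(D, D.T):
            raise ValidationError("distance matrix must be symmetric")
        if self.delta < 0 or self.m > self.max_val:
            raise ValidationError("need m <= max_val and delta >= 0")


@dataclass
class MDGraph:
    """Unweighted, undirected sample graph with node features and labels."""

    adjacency: np.ndarray
    node_features: np.ndarray
    node_labels: np.ndarray
    sample_ids: list[str]
    feature_names: list[str]
    tau: int | None = None
    tau_sick: int | None = None
    tau_healthy: int | None = None
    perc_val: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=np.int8)
        self.node_features = np.asarray(self.node_features, dtype=float)
        self.node_labels = np.asarray(self.node_labels, dtype=int)

    def validate(self) -> None:
        A = self.adjacency
        n = A.shape[0]
        if A.shape != (n, n):
            raise ValidationError("adjacency must be square")
        if not np.array_equal(A, A.T):
            raise ValidationError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValidationError("adjacency diagonal must be 0")
        if not np.isin(A, (0, 1)).all():
            raise ValidationError("adjacency must be binary")
        if self.node_features.shape[0] != n or self.node_labels.shape[0] != n:
            raise ValidationError("features/labels must match the node count")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    def neighbors(self, v: int) -> np.ndarray:
        return np.nonzero(self.adjacency[v])[0]

    def __eq__(self, other) -> bool:
        if not isinstance(other, MDGraph):
            return NotImplemented
        return (
            np.array_equal(self.adjacency, other.adjacency)
            and np.array_equal(self.node_features, other.node_features)
            and np.array_equal(self.node_labels, other.node_labels)
            and self.sample_ids == other.sample_ids
        )


def compute_distance_matrix(table_or_features, metric: str = "cosine") -> DistanceArtifacts:
    """Pairwise dissimilarity matrix with threshold scalars.

    Cosine dissimilarity is ``1 - cos(f_i, f_j)``; a zero-norm feature vector
    is assigned dissimilarity 1 to every non-zero vector and 0 to another
    zero vector (the cosine is undefined there, so maximal ignorance is
    assumed between unlike pairs and identity between all-zero pairs).

    The median m is taken over the N(N-1)/2 unordered off-diagonal pairs:
    the structurally-zero diagonal would otherwise bias the threshold low.
    """
    if metric not in _METRICS:
        raise ConfigurationError(f"unknown metric {metric!r}; choose from {sorted(_METRICS)}")
    X = table_or_features.features if isinstance(table_or_features, OTUTable) else np.asarray(
        table_or_features, dtype=float
    )
    if not np.all(np.isfinite(X)):
        raise ValidationError("features contain NaN/inf")
    vec = pdist(X, metric=_METRICS[metric])
    if metric == "cosine":
        zero = np.linalg.norm(X, axis=1) == 0
        if zero.any():
            vec = squareform(vec, checks=False)
            D = np.where(np.isnan(vec), 1.0, vec)
            D[np.ix_(zero, zero)] = 0.0
            np.fill_diagonal(D, 0.0)
            vec = squareform(D, checks=False)
        np.clip(vec, 0.0, None, out=vec)
    D = squareform(vec)
    m = float(np.median(vec))
    max_val = float(vec.max())
    return DistanceArtifacts(D=D, metric=metric, m=m, max_val=max_val, t=m,
                             delta=(max_val - m) / 5.0)


def neighbor_caps(
    table_or_labels, perc_val: float, imbalanced: bool
) -> int | tuple[int, int]:
    """Neighbor cap(s) from the sample counts.

    Balanced: ``tau = floor(perc_val * N / 100)``.  Imbalanced:
    ``tau_sick = floor(perc_val * n_sick / 100)`` and likewise for healthy.
    A cap that floors to 0 is raised to 1 (a node must be allowed at least
    one neighbor), with a warning.
    """
    if not (0 < perc_val <= 100):
        raise ConfigurationError("perc_val must lie in (0, 100]")
    labels = (
        table_or_labels.labels
        if isinstance(table_or_labels, OTUTable)
        else np.asarray(table_or_labels, dtype=int)
    )

    def _cap(count: int, what: str) -> int:
        cap = int(np.floor(perc_val * count / 100.0))
        if cap < 1:
            logger.warning("neighbor cap for %s floored to 0; raising to 1", what)
            cap = 1
        return cap

    if imbalanced:
        n_sick = int(np.sum(labels == SICK))
        n_healthy = int(np.sum(labels == HEALTHY))
        return _cap(n_sick, "sick"), _cap(n_healthy, "healthy")
    return _cap(labels.shape[0], "all samples")


def _caps_per_node(caps, labels: np.ndarray, n: int) -> np.ndarray:
    if isinstance(caps, tuple):
        tau_sick, tau_healthy = caps
        if labels is None:
            raise ConfigurationError("labels are required for class-specific caps")
        return np.where(np.asarray(labels) == SICK, tau_sick, tau_healthy).astype(int)
    return np.full(n, int(caps), dtype=int)


def _sorted_candidates(D: np.ndarray, i: int) -> np.ndarray:
    """Candidate walk order for node i: ascending distance, ties broken by
    ascending node index; self excluded (its zero distance would always pass)."""
    n = D.shape[0]
    others = np.concatenate([np.arange(i), np.arange(i + 1, n)])
    return others[np.argsort(D[i, others], kind="stable")]


def _walk(
    A: np.ndarray,
    D: np.ndarray,
    i: int,
    t: float,
    cap: int,
    count: int,
    accepted: set[int],
) -> int:
    """One construction walk for node i at threshold t.

    Accepts candidates in sorted order while ``d <= t`` and ``count < cap``;
    every acceptance sets the (idempotent) undirected edge and increments
    the initiated count, pre-existing or not.  Returns the updated count.
    """
    for j in _sorted_candidates(D, i):
        if count >= cap:
            break
        if D[i, j] > t:
            break  # sorted order: no later candidate can qualify
        if j in accepted:
            continue
        A[i, j] = 1
        A[j, i] = 1
        accepted.add(j)
        count += 1
    return count


@dataclass
class _WalkState:
    """Per-node initiated counts and accepted sets, carried into refinement."""

    counts: np.ndarray
    accepted: list[set]
    caps: np.ndarray
    t: float


def construct_edges(
    dist: DistanceArtifacts,
    caps,
    labels: np.ndarray | None = None,
    imbalanced: bool = False,
) -> tuple[np.ndarray, "_WalkState"]:
    """First-pass edge construction at t = m.

    Nodes are processed in index order; each walks its distance-sorted
    candidate list and initiates edges while under its cap.  The cap of the
    *initiating* node applies (its own label selects tau_sick/tau_healthy
    in the imbalanced regime); no constraint is placed on the neighbor.
    Returns the adjacency and the walk state for :func:`refine_edges`.
    """
    dist.validate()
    n = dist.D.shape[0]
    if imbalanced and not isinstance(caps, tuple):
        raise ConfigurationError("imbalanced construction needs (tau_sick, tau_healthy)")
    caps_vec = _caps_per_node(caps, labels, n)
    A = np.zeros((n, n), dtype=np.int8)
    counts = np.zeros(n, dtype=int)
    accepted: list[set] = [set() for _ in range(n)]
    for i in range(n):
        counts[i] = _walk(A, dist.D, i, dist.t, caps_vec[i], 0, accepted[i])
    return A, _WalkState(counts=counts, accepted=accepted, caps=caps_vec, t=dist.t)


def refine_edges(
    A: np.ndarray,
    dist: DistanceArtifacts,
    state: "_WalkState",
    min_degree: int | None = None,
) -> tuple[np.ndarray, float]:
    """Rescue standalone and sparse nodes by raising t in steps of delta.

    S is the set of nodes whose initiated count is below target (the full
    cap by default; ``min_degree`` substitutes a laxer target, e.g. 1 to
    rescue only standalone nodes).  For each node in S, t is raised by
    delta and the construction walk re-run for that node alone, at most 5
    times; the raised t is shared across rescued nodes and after the 5th
    increment t is clamped to max_val so every remaining candidate
    qualifies.  Returns the refined adjacency and the final t.
    """
    n = A.shape[0]
    if np.any(state.caps > n - 1):
        bad = int(state.caps.max())
        raise ConfigurationError(
            f"neighbor cap {bad} exceeds the {n - 1} possible neighbors; "
            "lower perc_val"
        )
    targets = state.caps if min_degree is None else np.minimum(state.caps, min_degree)
    t = state.t
    increments = 0
    sparse = [i for i in range(n) if state.counts[i] < targets[i]]
    for i in sparse:
        while state.counts[i] < targets[i] and increments < 5:
            t += dist.delta
            increments += 1
            if increments == 5:
                t = max(t, dist.max_val)  # guard fp shortfall of 5*delta
            state.counts[i] = _walk(
                A, dist.D, i, t, state.caps[i], state.counts[i], state.accepted[i]
            )
        # later nodes see the already-raised t
        if state.counts[i] < targets[i] and increments >= 5:
            state.counts[i] = _walk(
                A, dist.D, i, t, state.caps[i], state.counts[i], state.accepted[i]
            )
    state.t = t
    return A, t


def build_md_graph(table: OTUTable, config: RunConfig) -> MDGraph:
    """Distance matrix -> caps -> construction -> refinement -> feature attach.

    With ``config.blind_caps`` the single balanced tau is used even for
    imbalanced data, so construction never reads node labels (the
    class-aware default mirrors the transductive setting, where all labels
    shape the graph).
    """
    dist = compute_distance_matrix(table, config.metric)
    imbalanced = config.imbalanced and not config.blind_caps
    caps = neighbor_caps(table, config.perc_val, imbalanced)
    A, state = construct_edges(dist, caps, labels=table.labels, imbalanced=imbalanced)
    A, t_final = refine_edges(A, dist, state, min_degree=config.min_degree)
    tau = caps if not isinstance(caps, tuple) else None
    tau_sick, tau_healthy = caps if isinstance(caps, tuple) else (None, None)
    graph = MDGraph(
        adjacency=A,
        node_features=table.features,
        node_labels=table.labels,
        sample_ids=list(table.sample_ids),
        feature_names=list(table.feature_names),
        tau=tau,
        tau_sick=tau_sick,
        tau_healthy=tau_healthy,
        perc_val=config.perc_val,
        meta={
            "metric": config.metric,
            "perc_val": float(config.perc_val),
            "imbalanced": bool(imbalanced),
            "t_initial": float(dist.m),
            "t_final": float(t_final),
            "delta": float(dist.delta),
        },
    )
    graph.validate()
    return graph


def inspect_neighbors(
    graph: MDGraph, node_ids: list[str], dist: DistanceArtifacts | None = None
) -> dict:
    """Neighbor listing for the given sample ids.

    Per node: neighbor ids, labels and (if a distance matrix is supplied)
    distances, sorted ascending by distance; plus the same-label neighbor
    fraction summarising graph homophily around that node.
    """
    index = {s: i for i, s in enumerate(graph.sample_ids)}
    out = {}
    for sid in node_ids:
        if sid not in index:
            raise KeyError(f"unknown sample id {sid!r}")
        v = index[sid]
        nbrs = graph.neighbors(v)
        if dist is not None:
            order = np.argsort(dist.D[v, nbrs], kind="stable")
            nbrs = nbrs[order]
            dists = dist.D[v, nbrs].tolist()
        else:
            dists = [None] * len(nbrs)
        labels = graph.node_labels[nbrs]
        same = float(np.mean(labels == graph.node_labels[v])) if len(nbrs) else float("nan")
        out[sid] = {
            "neighbors": [graph.sample_ids[j] for j in nbrs],
            "labels": labels.tolist(),
            "distances": dists,
            "same_label_fraction": same,
        }
    return out
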
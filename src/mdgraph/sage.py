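"""GraphSAGE node classifier (mean aggregator) in plain numpy.

Each of K graph-convolution layers samples a fixed number S_k of neighbors
per node, takes the elementwise mean of their previous-layer
representations, concatenates that with the node's own representation,
applies a linear map and a nonlinearity, and L2-normalises the result
(guarding against gradient explosion).  A linear+softmax head on the K-th
representation yields class probabilities.  Training minimises (optionally
per-node weighted) categorical cross-entropy with Adam; gradients are
derived by hand, which keeps the dependency surface to numpy alone.

Layer-0 representations are the raw OTU abundance vectors.  Because ReLU
is positively homogeneous and every layer output is L2-normalised, the
representations are invariant to a global rescaling of the input table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import ConfigurationError, ValidationError
from .graph import MDGraph

__all__ = [
    "SageConfig",
    "SageModel",
    "sample_neighborhood",
    "mean_aggregate",
    "layer_forward",
    "forward",
    "train_sage",
]

logger = logging.getLogger(__name__)

_ACTIVATIONS = {
    "relu": (lambda z: np.maximum(z, 0.0), lambda z: (z > 0).astype(float)),
    "linear": (lambda z: z, lambda z: np.ones_like(z)),
}


@dataclass
class SageConfig:
    """GraphSAGE hyperparameters.

    Defaults are the selected settings for the disease-graph task: K=2
    layers of 32 hidden units, neighbor sample sizes (10, 5), ReLU, softmax
    output, 50 epochs of Adam at learning rate 5e-3, categorical
    cross-entropy loss.
    """

    num_layers: int = 2
    hidden_units: int = 32
    sample_sizes: tuple[int, ...] = (10, 5)
    activation: str = "relu"
    epochs: int = 50
    learning_rate: float = 5e-3
    optimizer: str = "adam"
    loss: str = "categorical_crossentropy"
    resample_per_epoch: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.sample_sizes = tuple(int(s) for s in self.sample_sizes)
        if self.num_layers < 1:
            raise ConfigurationError("need num_layers >= 1")
        if len(self.sample_sizes) != self.num_layers:
            raise ConfigurationError("sample_sizes must list one size per layer")
        if any(s < 1 for s in self.sample_sizes):
            raise ConfigurationError("sample sizes must be >= 1")
        if self.epochs < 1 or self.learning_rate <= 0:
            raise ConfigurationError("need epochs >= 1 and learning_rate > 0")
        if self.activation not in _ACTIVATIONS:
            raise ConfigurationError(f"unknown activation {self.activation!r}")
        if self.optimizer != "adam":
            raise ConfigurationError("only the adam optimizer is implemented")


@dataclass
class SageModel:
    """Trained GraphSAGE parameters: K conv weight matrices plus the
    linear+softmax output head."""

    conv_weights: list[np.ndarray]      # W^k, shape (2 * d_in_k, hidden)
    out_weight: np.ndarray              # (hidden, 2)
    out_bias: np.ndarray                # (2,)
    config: SageConfig
    loss_history: list[float] = field(default_factory=list)
    n_features: int = 0

    def validate(self) -> None:
        d = self.n_features
        for k, W in enumerate(self.conv_weights):
            if W.shape != (2 * d, self.config.hidden_units):
                raise ValidationError(f"layer {k}: weight shape {W.shape} inconsistent")
            d = self.config.hidden_units
        if self.out_weight.shape != (self.config.hidden_units, 2):
            raise ValidationError("output head shape inconsistent")


def sample_neighborhood(
    graph: MDGraph, v: int, S: int, rng: np.random.Generator
) -> np.ndarray:
    """Fixed-size sampled neighborhood N(v), self excluded.

    degree >= S: S distinct neighbors without replacement; 0 < degree < S:
    S draws with replacement (a multiset); degree == 0: the node itself
    (fallback so the aggregation never sees an empty set).
    """
    if S < 1:
        raise ConfigurationError("sample size S must be >= 1")
    nbrs = graph.neighbors(v)
    if len(nbrs) == 0:
        return np.array([v], dtype=int)
    if len(nbrs) >= S:
        return rng.choice(nbrs, size=S, replace=False)
    return rng.choice(nbrs, size=S, replace=True)


def mean_aggregate(vectors: np.ndarray) -> np.ndarray:
    """Multiplicity-weighted elementwise mean of a non-empty stack of vectors."""
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim == 1:
        vectors = vectors[None, :]
    if vectors.shape[0] == 0:
        raise ValidationError("mean_aggregate needs a non-empty multiset")
    return vectors.mean(axis=0)


def _l2_normalize(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    norms = np.linalg.norm(A, axis=-1, keepdims=True)
    safe = np.where(norms == 0, 1.0, norms)
    return A / safe, norms


def layer_forward(
    h_self: np.ndarray, h_agg: np.ndarray, W: np.ndarray, activation: str = "relu"
) -> np.ndarray:
    """One GraphSAGE layer for a single node (or a batch of rows):
    ``l2norm(act(W . concat(h_self, h_agg)))``; an exactly-zero activation
    vector is returned unchanged rather than divided by zero."""
    act, _ = _ACTIVATIONS[activation]
    h_self = np.atleast_2d(np.asarray(h_self, dtype=float))
    h_agg = np.atleast_2d(np.asarray(h_agg, dtype=float))
    C = np.concatenate([h_self, h_agg], axis=-1)
    if C.shape[-1] != W.shape[0]:
        raise ValidationError(
            f"concatenated width {C.shape[-1]} does not match W rows {W.shape[0]}"
        )
    H, _ = _l2_normalize(act(C @ W))
    return H[0] if H.shape[0] == 1 else H


def _sampling_matrix(graph: MDGraph, S: int, rng: np.random.Generator) -> np.ndarray:
    """Row-stochastic N x N matrix; row v averages v's sampled neighborhood."""
    n = graph.n_nodes
    M = np.zeros((n, n))
    for v in range(n):
        sample = sample_neighborhood(graph, v, S, rng)
        idx, counts = np.unique(sample, return_counts=True)
        M[v, idx] = counts / len(sample)
    return M


def _softmax(Z: np.ndarray) -> np.ndarray:
    Z = Z - Z.max(axis=1, keepdims=True)
    E = np.exp(Z)
    return E / E.sum(axis=1, keepdims=True)


def _forward_full(
    model: SageModel, graph: MDGraph, rng: np.random.Generator, caches: list | None = None
) -> np.ndarray:
    """Full-graph forward pass; optionally records per-layer caches for backprop."""
    act, _ = _ACTIVATIONS[model.config.activation]
    H = graph.node_features.astype(float)
    for k, W in enumerate(model.conv_weights):
        M = _sampling_matrix(graph, model.config.sample_sizes[k], rng)
        C = np.concatenate([H, M @ H], axis=1)
        Z = C @ W
        A = act(Z)
        Hn, norms = _l2_normalize(A)
        if caches is not None:
            caches.append((M, C, Z, Hn, norms))
        H = Hn
    logits = H @ model.out_weight + model.out_bias
    P = _softmax(logits)
    if caches is not None:
        caches.append((H, P))
    return P


def forward(
    model: SageModel,
    graph: MDGraph,
    nodes: np.ndarray | list[int] | None = None,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Class-probability pairs (healthy, sick) for the requested nodes.

    Neighborhoods are resampled for the call, so an explicit ``rng`` (or
    integer seed) makes predictions reproducible.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(model.config.seed if rng is None else rng)
    P = _forward_full(model, graph, rng)
    if nodes is None:
        return P
    return P[np.asarray(nodes, dtype=int)]


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr, self.b1, self.b2, self.eps = lr, 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _init_model(config: SageConfig, n_features: int, rng: np.random.Generator) -> SageModel:
    """Glorot-uniform initialisation scaled by fan-in/fan-out."""
    conv = []
    d = n_features
    for _ in range(config.num_layers):
        fan_in, fan_out = 2 * d, config.hidden_units
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        conv.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        d = config.hidden_units
    limit = np.sqrt(6.0 / (d + 2))
    out_w = rng.uniform(-limit, limit, size=(d, 2))
    out_b = np.zeros(2)
    return SageModel(conv_weights=conv, out_weight=out_w, out_bias=out_b,
                     config=config, n_features=n_features)


def train_sage(
    graph: MDGraph,
    train_nodes: np.ndarray | list[int],
    sample_weights: np.ndarray | None = None,
    config: SageConfig | None = None,
) -> SageModel:
    """Train a GraphSAGE classifier on the labeled train nodes.

    ``train_nodes`` may contain repeats (e.g. a bootstrap multiset);
    occurrences are aggregated into per-node loss weights, so duplicating a
    node is identical to doubling its sample weight.  The loss is the
    weight-normalised categorical cross-entropy over the train nodes;
    neighborhoods are resampled every epoch unless
    ``config.resample_per_epoch`` is off.
    """
    config = config or SageConfig()
    train_nodes = np.asarray(train_nodes, dtype=int)
    if train_nodes.size == 0:
        raise ValidationError("train_nodes must be non-empty")
    if sample_weights is None:
        sample_weights = np.ones(train_nodes.shape[0])
    sample_weights = np.asarray(sample_weights, dtype=float)
    if sample_weights.shape != train_nodes.shape:
        raise ValidationError("sample_weights must align with train_nodes")
    if np.any(sample_weights < 0) or sample_weights.sum() <= 0:
        raise ValidationError("sample_weights must be non-negative with positive sum")

    n = graph.n_nodes
    # aggregate multiset occurrences into one weight per unique node
    w_node = np.zeros(n)
    np.add.at(w_node, train_nodes, sample_weights)
    w_node /= w_node.sum()
    labels = graph.node_labels
    if len(np.unique(labels[np.unique(train_nodes)])) < 2:
        warnings.warn("train set contains a single class; training proceeds", stacklevel=2)
    Y = np.zeros((n, 2))
    Y[np.arange(n), labels] = 1.0

    rng = np.random.default_rng(config.seed)
    model = _init_model(config, graph.node_features.shape[1], rng)
    params = [*model.conv_weights, model.out_weight, model.out_bias]
    opt = _Adam(params, config.learning_rate)
    _, act_grad = _ACTIVATIONS[config.activation]

    sample_rng = rng if config.resample_per_epoch else np.random.default_rng(config.seed + 1)
    frozen_caches = None
    for epoch in range(config.epochs):
        caches: list = []
        if config.resample_per_epoch or frozen_caches is None:
            P = _forward_full(model, graph, sample_rng, caches)
            if not config.resample_per_epoch:
                frozen_caches = [c[0] for c in caches[:-1]]  # keep sampling matrices
        else:
            # rebuild forward with frozen sampling matrices
            H = graph.node_features.astype(float)
            caches = []
            for k, W in enumerate(model.conv_weights):
                M = frozen_caches[k]
                C = np.concatenate([H, M @ H], axis=1)
                Z = C @ W
                A = _ACTIVATIONS[config.activation][0](Z)
                Hn, norms = _l2_normalize(A)
                caches.append((M, C, Z, Hn, norms))
                H = Hn
            logits = H @ model.out_weight + model.out_bias
            P = _softmax(logits)
            caches.append((H, P))

        HK, P = caches[-1]
        eps = 1e-12
        loss = float(-np.sum(w_node * np.log(P[np.arange(n), labels] + eps)))
        model.loss_history.append(loss)

        # ---- backward ----
        dlogits = (P - Y) * w_node[:, None]
        g_out_w = HK.T @ dlogits
        g_out_b = dlogits.sum(axis=0)
        dH = dlogits @ model.out_weight.T
        g_conv: list[np.ndarray] = [None] * config.num_layers  # type: ignore
        for k in range(config.num_layers - 1, -1, -1):
            M, C, Z, Hn, norms = caches[k]
            # through L2 normalisation (identity on exactly-zero rows)
            safe = np.where(norms == 0, 1.0, norms)
            dA = (dH - Hn * np.sum(Hn * dH, axis=1, keepdims=True)) / safe
            dZ = dA * act_grad(Z)
            g_conv[k] = C.T @ dZ
            dC = dZ @ model.conv_weights[k].T
            d_in = C.shape[1] // 2
            dH = dC[:, :d_in] + M.T @ dC[:, d_in:]

        opt.step(params, [*g_conv, g_out_w, g_out_b])

    logger.debug("train_sage: final loss %.4f after %d epochs", loss, config.epochs)
    return model
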
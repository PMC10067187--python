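"""Scikit-learn style estimators wrapping the MD-graph + GraphSAGE pipeline.

The classifiers are transductive, following the convention of
:class:`sklearn.semi_supervised.LabelPropagation`: ``fit(X, y)`` receives
the FULL cohort, with ``-1`` marking unlabeled samples, builds the MD-graph
over all rows, trains on the labeled ones, and exposes predictions for
every node in ``transduction_``.  Alternatively, pass a fully labeled ``y``
together with ``unlabeled_mask`` to hide a subset from training while still
letting their labels shape the class-aware neighbor caps (the transductive
construction used for imbalanced cohorts; leakage-free behaviour is
available via ``blind_caps=True``).

``predict(X)`` on unseen rows works inductively: each new sample is
attached to the fitted graph through the same distance threshold (up to the
balanced neighbor cap, falling back to the single nearest fitted sample)
and pushed through the trained model, which GraphSAGE's sampled
aggregation supports by design.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted

from ._seeds import child_seed
from .boosting import BoostConfig, ensemble_predict, fit_boosted
from .graph import (
    DistanceArtifacts,
    MDGraph,
    compute_distance_matrix,
    construct_edges,
    neighbor_caps,
    refine_edges,
)
from .io import HEALTHY, SICK, ValidationError
from .sage import SageConfig, forward, train_sage

__all__ = ["GraphSAGEClassifier", "BoostedGraphSAGEClassifier"]

_UNLABELED = -1


class _BaseMDGraphClassifier(ClassifierMixin, BaseEstimator):
    """Shared graph construction, transduction bookkeeping and inductive attach."""

    def _more_tags(self):  # pragma: no cover - sklearn plumbing
        return {"requires_y": True, "binary_only": True}

    # subclasses set: metric, perc_val, imbalanced, blind_caps, random_state, ...

    def _validate_fit_args(self, X, y, unlabeled_mask):
        X = check_array(X, dtype=float, ensure_min_samples=2)
        y = np.asarray(y, dtype=int)
        if y.shape[0] != X.shape[0]:
            raise ValidationError("X and y must have the same number of rows")
        bad = set(np.unique(y)) - {HEALTHY, SICK, _UNLABELED}
        if bad:
            raise ValidationError(f"y must contain only 0, 1 and -1; got extra {sorted(bad)}")
        if unlabeled_mask is not None:
            unlabeled_mask = np.asarray(unlabeled_mask, dtype=bool)
            if unlabeled_mask.shape != y.shape:
                raise ValidationError("unlabeled_mask must align with y")
        else:
            unlabeled_mask = np.zeros_like(y, dtype=bool)
        labeled = (y != _UNLABELED) & ~unlabeled_mask
        if not labeled.any():
            raise ValidationError("no labeled samples to train on")
        return X, y, labeled

    def _build_graph(self, X, y, labeled):
        known = y != _UNLABELED
        imbalanced = self.imbalanced and not self.blind_caps
        if imbalanced and not known.all():
            warnings.warn(
                "imbalanced caps need labels for every node; falling back to the "
                "balanced cap (blind construction) for this fit",
                stacklevel=3,
            )
            imbalanced = False
        dist = compute_distance_matrix(X, self.metric)
        node_labels = np.where(known, y, HEALTHY)
        caps = neighbor_caps(node_labels if imbalanced else np.zeros(X.shape[0], int),
                             self.perc_val, imbalanced)
        A, state = construct_edges(dist, caps, labels=node_labels, imbalanced=imbalanced)
        A, t_final = refine_edges(A, dist, state)
        tau_sick, tau_healthy = caps if isinstance(caps, tuple) else (None, None)
        graph = MDGraph(
            adjacency=A,
            node_features=X,
            node_labels=node_labels,
            sample_ids=[f"S{i:05d}" for i in range(X.shape[0])],
            feature_names=[f"OTU{j:04d}" for j in range(X.shape[1])],
            tau=None if isinstance(caps, tuple) else caps,
            tau_sick=tau_sick,
            tau_healthy=tau_healthy,
            perc_val=self.perc_val,
            meta={"metric": self.metric, "t_initial": dist.m, "t_final": t_final,
                  "imbalanced": bool(imbalanced)},
        )
        graph.validate()
        # balanced cap governs inductive attachment of unseen samples
        attach_cap = graph.tau if graph.tau is not None else neighbor_caps(
            np.zeros(X.shape[0], int), self.perc_val, False
        )
        return dist, graph, attach_cap

    def _attach(self, X_new: np.ndarray) -> tuple[MDGraph, np.ndarray]:
        """Augment the fitted graph with unseen rows connected through the
        final distance threshold; returns (augmented graph, new node ids)."""
        D_new = cdist(X_new, self.graph_.node_features,
                      metric={"euclidean": "euclidean", "manhattan": "cityblock",
                              "cosine": "cosine"}[self.metric])
        if self.metric == "cosine":
            zero_new = np.linalg.norm(X_new, axis=1) == 0
            zero_old = np.linalg.norm(self.graph_.node_features, axis=1) == 0
            D_new = np.where(np.isnan(D_new), 1.0, D_new)
            D_new[np.ix_(zero_new, zero_old)] = 0.0
            np.clip(D_new, 0.0, None, out=D_new)
        n_old = self.graph_.n_nodes
        n_new = X_new.shape[0]
        t = float(self.graph_.meta.get("t_final"))
        A = np.zeros((n_old + n_new, n_old + n_new), dtype=np.int8)
        A[:n_old, :n_old] = self.graph_.adjacency
        for i in range(n_new):
            order = np.argsort(D_new[i], kind="stable")
            within = order[D_new[i, order] <= t][: self._attach_cap_]
            if within.size == 0:
                within = order[:1]  # nearest fitted sample as a fallback
            A[n_old + i, within] = 1
            A[within, n_old + i] = 1
        graph = MDGraph(
            adjacency=A,
            node_features=np.vstack([self.graph_.node_features, X_new]),
            node_labels=np.concatenate([self.graph_.node_labels,
                                        np.zeros(n_new, dtype=int)]),
            sample_ids=self.graph_.sample_ids + [f"Q{i:05d}" for i in range(n_new)],
            feature_names=self.graph_.feature_names,
            meta=dict(self.graph_.meta),
        )
        return graph, np.arange(n_old, n_old + n_new)

    def _is_fit_data(self, X: np.ndarray) -> bool:
        return X.shape == self._fit_X_.shape and np.array_equal(X, self._fit_X_)

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "graph_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValidationError(
                f"X has {X.shape[1]} features; the model was fitted with "
                f"{self.n_features_in_}"
            )
        if self._is_fit_data(X):
            return self.transduction_.copy()
        return self._predict_new(X)[0]

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "graph_")
        X = check_array(X, dtype=float)
        if self._is_fit_data(X):
            s = self.decision_scores_
        else:
            s = self._predict_new(X)[1]
        return np.column_stack([1.0 - s, s])


class GraphSAGEClassifier(_BaseMDGraphClassifier):
    """Single GraphSAGE node classifier on the MD-graph.

    Parameters mirror the selected task settings: two 32-unit mean-aggregator
    layers with neighbor sample sizes (10, 5), ReLU, 50 epochs of Adam at
    5e-3, softmax output.  See the module docstring for the transductive
    ``fit`` conventions.
    """

    def __init__(
        self,
        metric: str = "cosine",
        perc_val: float = 10.0,
        imbalanced: bool = False,
        blind_caps: bool = False,
        num_layers: int = 2,
        hidden_units: int = 32,
        sample_sizes: tuple[int, ...] = (10, 5),
        activation: str = "relu",
        epochs: int = 50,
        learning_rate: float = 5e-3,
        resample_per_epoch: bool = True,
        random_state: int = 0,
    ):
        self.metric = metric
        self.perc_val = perc_val
        self.imbalanced = imbalanced
        self.blind_caps = blind_caps
        self.num_layers = num_layers
        self.hidden_units = hidden_units
        self.sample_sizes = sample_sizes
        self.activation = activation
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.resample_per_epoch = resample_per_epoch
        self.random_state = random_state

    def _sage_config(self, seed: int) -> SageConfig:
        return SageConfig(
            num_layers=self.num_layers,
            hidden_units=self.hidden_units,
            sample_sizes=tuple(self.sample_sizes),
            activation=self.activation,
            epochs=self.epochs,
            learning_rate=self.learning_rate,
            resample_per_epoch=self.resample_per_epoch,
            seed=seed,
        )

    def fit(self, X, y, unlabeled_mask=None):
        X, y, labeled = self._validate_fit_args(X, y, unlabeled_mask)
        self._fit_X_ = X
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.array([HEALTHY, SICK])
        dist, graph, attach_cap = self._build_graph(X, y, labeled)
        self.dist_ = dist
        self.graph_ = graph
        self._attach_cap_ = attach_cap
        self.model_ = train_sage(
            graph,
            np.nonzero(labeled)[0],
            config=self._sage_config(child_seed(self.random_state, "sage")),
        )
        P = forward(self.model_, graph,
                    rng=child_seed(self.random_state, "predict"))
        self.transduction_ = np.argmax(P, axis=1)
        self.decision_scores_ = P[:, SICK]
        return self

    def _predict_new(self, X_new):
        graph, new_ids = self._attach(X_new)
        P = forward(self.model_, graph, new_ids,
                    rng=child_seed(self.random_state, "predict", 1))
        return np.argmax(P, axis=1), P[:, SICK]


class BoostedGraphSAGEClassifier(_BaseMDGraphClassifier):
    """AdaBoost ensemble of GraphSAGE node classifiers on the MD-graph.

    ``n_estimators`` defaults to 10 (the selected value for the imbalanced
    IBD-style cohort; 15 suits the balanced CRC-style cohort).  Rounds whose
    base learner cannot beat chance on the weighted train set are discarded
    and redrawn up to ``max_retries`` times.
    """

    def __init__(
        self,
        metric: str = "cosine",
        perc_val: float = 10.0,
        imbalanced: bool = False,
        blind_caps: bool = False,
        n_estimators: int = 10,
        max_retries: int = 5,
        epsilon_floor: float = 1e-10,
        num_layers: int = 2,
        hidden_units: int = 32,
        sample_sizes: tuple[int, ...] = (10, 5),
        activation: str = "relu",
        epochs: int = 50,
        learning_rate: float = 5e-3,
        resample_per_epoch: bool = True,
        random_state: int = 0,
    ):
        self.metric = metric
        self.perc_val = perc_val
        self.imbalanced = imbalanced
        self.blind_caps = blind_caps
        self.n_estimators = n_estimators
        self.max_retries = max_retries
        self.epsilon_floor = epsilon_floor
        self.num_layers = num_layers
        self.hidden_units = hidden_units
        self.sample_sizes = sample_sizes
        self.activation = activation
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.resample_per_epoch = resample_per_epoch
        self.random_state = random_state

    def fit(self, X, y, unlabeled_mask=None):
        X, y, labeled = self._validate_fit_args(X, y, unlabeled_mask)
        self._fit_X_ = X
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.array([HEALTHY, SICK])
        dist, graph, attach_cap = self._build_graph(X, y, labeled)
        self.dist_ = dist
        self.graph_ = graph
        self._attach_cap_ = attach_cap
        sage_config = SageConfig(
            num_layers=self.num_layers,
            hidden_units=self.hidden_units,
            sample_sizes=tuple(self.sample_sizes),
            activation=self.activation,
            epochs=self.epochs,
            learning_rate=self.learning_rate,
            resample_per_epoch=self.resample_per_epoch,
            seed=child_seed(self.random_state, "sage"),
        )
        boost_config = BoostConfig(
            n_estimators=self.n_estimators,
            max_retries=self.max_retries,
            epsilon_floor=self.epsilon_floor,
            seed=child_seed(self.random_state, "boost"),
        )
        self.ensemble_ = fit_boosted(graph, np.nonzero(labeled)[0],
                                     boost_config, sage_config)
        labels, scores = ensemble_predict(
            self.ensemble_, graph, rng=child_seed(self.random_state, "predict")
        )
        self.transduction_ = labels
        self.decision_scores_ = scores
        return self

    def _predict_new(self, X_new):
        graph, new_ids = self._attach(X_new)
        return ensemble_predict(
            self.ensemble_, graph, new_ids,
            rng=child_seed(self.random_state, "predict", 1),
        )
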
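"""Readers/writers and core data types for OTU tables, graphs and run configuration.

An OTU table is a delimited text file (CSV or TSV, header row) with one row
per sample, one column per OTU feature, and one label column coding the
disease state.  Internally labels are always healthy=0 / sick=1; the +/-1
coding needed by weighted-majority voting is derived as ``2*y - 1`` at
prediction time.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "OTUTable",
    "RunConfig",
    "read_otu_table",
    "write_otu_table",
    "read_graph",
    "write_graph",
    "load_config",
    "save_config",
]

HEALTHY, SICK = 0, 1

#: default mapping from raw label strings to the internal coding
DEFAULT_LABEL_MAP: Mapping[str, int] = {
    "healthy": HEALTHY,
    "h": HEALTHY,
    "control": HEALTHY,
    "0": HEALTHY,
    "sick": SICK,
    "s": SICK,
    "disease": SICK,
    "case": SICK,
    "1": SICK,
}


class ValidationError(ValueError):
    """Input data violates a structural invariant."""


class ConfigurationError(ValueError):
    """Run configuration or call arguments are inconsistent."""


@dataclass
class OTUTable:
    """Sample x OTU abundance matrix with per-sample binary labels.

    Attributes
    ----------
    sample_ids : list of str
        Unique sample identifiers, one per row.
    features : ndarray of shape (N, f)
        Non-negative abundances (raw counts or relative abundances; the
        package never renormalises).
    feature_names : list of str
        One name per feature column.
    labels : ndarray of shape (N,)
        Internal coding healthy=0, sick=1.
    """

    sample_ids: list[str]
    features: np.ndarray
    feature_names: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.validate()

    def validate(self) -> None:
        n, f = self.features.shape
        if n < 2:
            raise ValidationError(f"need at least 2 samples, got {n}")
        if f < 1:
            raise ValidationError("need at least 1 feature")
        if len(self.sample_ids) != n or len(self.feature_names) != f:
            raise ValidationError("sample_ids/feature_names lengths do not match the matrix")
        if len(set(self.sample_ids)) != n:
            dup = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise ValidationError(f"duplicate sample ids: {dup[:5]}")
        if not np.all(np.isfinite(self.features)):
            raise ValidationError("abundances must be finite")
        if np.any(self.features < 0):
            i, j = np.argwhere(self.features < 0)[0]
            raise ValidationError(
                f"negative abundance at sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_names[j]!r}"
            )
        bad = set(np.unique(self.labels)) - {HEALTHY, SICK}
        if bad:
            raise ValidationError(f"labels must be 0 (healthy) or 1 (sick); got extra {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def n_sick(self) -> int:
        return int(np.sum(self.labels == SICK))

    @property
    def n_healthy(self) -> int:
        return int(np.sum(self.labels == HEALTHY))

    def __eq__(self, other) -> bool:
        if not isinstance(other, OTUTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.feature_names == other.feature_names
            and np.array_equal(self.features, other.features)
            and np.array_equal(self.labels, other.labels)
        )


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_otu_table(
    path: str | Path,
    label_column: str = "label",
    label_map: Mapping[str, int] | None = None,
    transpose: bool = False,
) -> OTUTable:
    """Read a delimited sample x OTU table with a label column.

    Parameters
    ----------
    path : path
        CSV/TSV file with a header row; first column holds sample ids.
    label_column : str
        Name of the column holding the disease-state label.
    label_map : mapping, optional
        Raw label value -> {0, 1}.  Defaults to a case-insensitive map
        accepting healthy/control/h/0 and sick/disease/case/s/1.
    transpose : bool
        Set when the file stores features as rows and samples as columns;
        the layout is never auto-detected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if transpose:
        df = df.T
    if label_column not in df.columns:
        raise ConfigurationError(
            f"label column {label_column!r} not found; columns include {list(df.columns[:5])}"
        )
    raw_labels = df[label_column]
    feat = df.drop(columns=[label_column])

    values = [str(v).strip() for v in raw_labels]
    distinct = sorted(set(values))
    if len(distinct) != 2:
        raise ValidationError(
            f"label column {label_column!r} must take exactly two values, got {distinct}"
        )
    if label_map is None:
        label_map = DEFAULT_LABEL_MAP
    lowered = {str(k).strip().lower(): v for k, v in label_map.items()}
    try:
        labels = np.array([lowered[v.lower()] for v in values], dtype=int)
    except KeyError as e:
        raise ConfigurationError(
            f"label value {e.args[0]!r} has no mapping to healthy=0/sick=1; "
            "pass an explicit label_map"
        ) from None

    try:
        features = feat.to_numpy(dtype=float)
    except (TypeError, ValueError):
        for col in feat.columns:
            coerced = pd.to_numeric(feat[col], errors="coerce")
            if coerced.isna().any():
                row = feat.index[coerced.isna()][0]
                raise ValidationError(
                    f"non-numeric abundance at sample {row!r}, feature {col!r}"
                ) from None
        raise

    return OTUTable(
        sample_ids=[str(s) for s in df.index],
        features=features,
        feature_names=[str(c) for c in feat.columns],
        labels=labels,
    )


def write_otu_table(table: OTUTable, path: str | Path, label_column: str = "label") -> None:
    """Write an OTU table to CSV/TSV (extension selects the delimiter)."""
    path = Path(path)
    df = pd.DataFrame(table.features, index=table.sample_ids, columns=table.feature_names)
    df[label_column] = table.labels
    df.index.name = "sample_id"
    df.to_csv(path, sep=_sep_for(path))


# ---------------------------------------------------------------------------
# Graph serialization: edge-list TSV + companion node-attribute CSV.
# ---------------------------------------------------------------------------

def _node_table_path(edge_path: Path) -> Path:
    return edge_path.with_name(edge_path.stem + ".nodes.csv")


def write_graph(graph, path: str | Path) -> None:
    """Write an MD-graph as an edge-list TSV plus a ``<stem>.nodes.csv`` table.

    Each undirected edge is written once, lexicographically smallest sample id
    first.  The node table carries sample ids, labels and the feature matrix.
    """
    from .graph import MDGraph  # local import to avoid a cycle

    assert isinstance(graph, MDGraph)
    path = Path(path)
    ids = graph.sample_ids
    lines = ["source\ttarget"]
    src, dst = np.nonzero(np.triu(graph.adjacency, k=1))
    for i, j in zip(src, dst):
        a, b = sorted((ids[i], ids[j]))
        lines.append(f"{a}\t{b}")
    path.write_text("\n".join(lines) + "\n")

    df = pd.DataFrame(graph.node_features, index=ids, columns=graph.feature_names)
    df.insert(0, "label", graph.node_labels)
    df.index.name = "sample_id"
    meta = dict(graph.meta)
    with open(_node_table_path(path), "w") as fh:
        if meta:
            fh.write("#meta " + json.dumps(meta) + "\n")
        df.to_csv(fh)


def read_graph(path: str | Path):
    """Read a graph written by :func:`write_graph`; inverse on adjacency,
    features, labels and ids."""
    from .graph import MDGraph

    path = Path(path)
    node_path = _node_table_path(path)
    with open(node_path) as fh:
        first = fh.readline()
        meta = {}
        if first.startswith("#meta "):
            meta = json.loads(first[len("#meta "):])
        else:
            fh.seek(0)
        df = pd.read_csv(fh, index_col=0)
    ids = [str(s) for s in df.index]
    index = {s: i for i, s in enumerate(ids)}
    labels = df["label"].to_numpy(dtype=int)
    features = df.drop(columns=["label"]).to_numpy(dtype=float)
    feature_names = [c for c in df.columns if c != "label"]

    n = len(ids)
    adj = np.zeros((n, n), dtype=np.int8)
    with open(path) as fh:
        header = fh.readline()
        if header.strip() != "source\ttarget":
            raise ValidationError(f"{path}: line 1: expected 'source\\ttarget' header")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValidationError(f"{path}: line {lineno}: malformed edge line {line!r}")
            a, b = parts
            if a not in index or b not in index:
                unknown = a if a not in index else b
                raise ValidationError(f"{path}: line {lineno}: unknown node id {unknown!r}")
            adj[index[a], index[b]] = 1
            adj[index[b], index[a]] = 1

    return MDGraph(
        adjacency=adj,
        node_features=features,
        node_labels=labels,
        sample_ids=ids,
        feature_names=feature_names,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """End-to-end run configuration (YAML-serialisable).

    Defaults mirror the framework's selected settings: cosine dissimilarity,
    a neighbor percentage of 10, two 32-unit GraphSAGE layers sampling 10
    then 5 neighbors, ReLU, 50 epochs of Adam at 5e-3, and 10 boosting
    rounds, with a stratified 70:15:15 train/validation/test node split.
    """

    metric: str = "cosine"
    perc_val: float = 10.0
    imbalanced: bool = False
    blind_caps: bool = False
    min_degree: int | None = None
    split_ratios: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0
    # GraphSAGE hyperparameters
    num_layers: int = 2
    hidden_units: int = 32
    sample_sizes: tuple[int, ...] = (10, 5)
    activation: str = "relu"
    epochs: int = 50
    learning_rate: float = 5e-3
    resample_per_epoch: bool = True
    # boosting hyperparameters
    n_estimators: int = 10
    max_retries: int = 5
    epsilon_floor: float = 1e-10

    def __post_init__(self) -> None:
        if self.metric not in {"euclidean", "manhattan", "cosine"}:
            raise ConfigurationError(f"unknown metric {self.metric!r}")
        if not (0 < self.perc_val <= 100):
            raise ConfigurationError("perc_val must lie in (0, 100]")
        if abs(sum(self.split_ratios) - 1.0) > 1e-9:
            raise ConfigurationError("split_ratios must sum to 1")
        if len(self.sample_sizes) != self.num_layers:
            raise ConfigurationError("sample_sizes must list one size per layer")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["split_ratios"] = list(self.split_ratios)
        d["sample_sizes"] = list(self.sample_sizes)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if "split_ratios" in d:
            d["split_ratios"] = tuple(d["split_ratios"])
        if "sample_sizes" in d:
            d["sample_sizes"] = tuple(d["sample_sizes"])
        return cls(**d)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def load_config(path: str | Path) -> RunConfig:
    return RunConfig.from_dict(yaml.safe_load(Path(path).read_text()))
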
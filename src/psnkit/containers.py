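"""Core in-memory containers shared across the package.

A *patient similarity network* (PSN) is an undirected weighted graph whose
nodes are patients and whose edge weights encode pairwise similarity under
one feature (a data type, a single variable, or a pathway's gene subset).
Every downstream step — network weighting, label propagation, feature
scoring, classification — consumes these containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "PatientDataLayer",
    "GeneSetCollection",
    "SimilarityNetwork",
    "edge_key",
    "validate_labels",
]


def edge_key(a: str, b: str) -> tuple[str, str]:
    """Canonical (lexicographically ordered) key for an undirected edge."""
    if a == b:
        raise ValueError(f"self-edge on node {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass
class PatientDataLayer:
    """One data type's patient-by-variable matrix.

    ``data`` is a float DataFrame indexed by patient ID with variable IDs as
    columns; NaN marks a missing measurement. Patient and variable IDs are
    case-sensitive opaque strings and must be unique.
    """

    name: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"layer {self.name!r}: duplicate patient IDs {dups}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"layer {self.name!r}: duplicate variable IDs {dups}")
        self.data = self.data.astype(float)
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def variable_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_patients(self) -> int:
        return self.data.shape[0]

    @property
    def n_variables(self) -> int:
        return self.data.shape[1]

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().sum().sum())

    def subset_patients(self, ids: Iterable[str]) -> "PatientDataLayer":
        ids = list(ids)
        missing = [i for i in ids if i not in self.data.index]
        if missing:
            raise KeyError(f"layer {self.name!r}: unknown patients {missing[:5]}")
        return PatientDataLayer(self.name, self.data.loc[ids].copy())

    def subset_variables(self, ids: Iterable[str]) -> "PatientDataLayer":
        return PatientDataLayer(self.name, self.data.loc[:, list(ids)].copy())


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. pathways) with per-set description text."""

    sets: dict[str, tuple[str, ...]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise ValueError(f"gene set {name!r} has no members")
            if len(set(members)) != len(members):
                # normalize: de-duplicate preserving order
                seen: dict[str, None] = {}
                for m in members:
                    seen.setdefault(m, None)
                self.sets[name] = tuple(seen)
        for name in self.sets:
            self.descriptions.setdefault(name, "")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


@dataclass
class SimilarityNetwork:
    """Undirected weighted patient graph for one feature.

    Edges are stored once per unordered pair, keyed by ``(a, b)`` with
    ``a < b``. Weights must be finite; metrics bounded on the unit interval
    (normalized similarity, exponential kernels) yield weights in [0, 1],
    while Pearson networks may carry negative raw weights until sparsified.
    """

    name: str
    nodes: tuple[str, ...]
    edges: dict[tuple[str, str], float]
    metric: str = ""

    def __post_init__(self) -> None:
        self.nodes = tuple(str(n) for n in self.nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError(f"network {self.name!r}: duplicate node IDs")
        node_set = set(self.nodes)
        clean: dict[tuple[str, str], float] = {}
        for (a, b), w in self.edges.items():
            key = edge_key(a, b)
            if key in clean and clean[key] != w:
                raise ValueError(f"network {self.name!r}: conflicting weights for {key}")
            if a not in node_set or b not in node_set:
                raise ValueError(f"network {self.name!r}: edge {key} outside node set")
            w = float(w)
            if not np.isfinite(w):
                raise ValueError(f"network {self.name!r}: non-finite weight on {key}")
            clean[key] = w
        self.edges = clean

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def weight(self, a: str, b: str, default: float | None = None) -> float | None:
        return self.edges.get(edge_key(a, b), default)

    def degrees(self) -> dict[str, int]:
        deg = {n: 0 for n in self.nodes}
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg

    def incident(self) -> dict[str, list[tuple[float, str]]]:
        """Per node, the list of (weight, partner) over incident edges."""
        inc: dict[str, list[tuple[float, str]]] = {n: [] for n in self.nodes}
        for (a, b), w in self.edges.items():
            inc[a].append((w, b))
            inc[b].append((w, a))
        return inc

    def subset(self, ids: Iterable[str], name: str | None = None) -> "SimilarityNetwork":
        keep = [i for i in ids]
        keep_set = set(keep)
        unknown = keep_set - set(self.nodes)
        if unknown:
            raise KeyError(f"network {self.name!r}: unknown nodes {sorted(unknown)[:5]}")
        edges = {k: w for k, w in self.edges.items() if k[0] in keep_set and k[1] in keep_set}
        return SimilarityNetwork(name or self.name, tuple(keep), edges, self.metric)

    def to_adjacency(self, order: Iterable[str] | None = None) -> np.ndarray:
        order = list(order) if order is not None else list(self.nodes)
        idx = {n: i for i, n in enumerate(order)}
        A = np.zeros((len(order), len(order)))
        for (a, b), w in self.edges.items():
            if a in idx and b in idx:
                A[idx[a], idx[b]] = w
                A[idx[b], idx[a]] = w
        return A

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph(name=self.name)
        g.add_nodes_from(self.nodes)
        for (a, b), w in self.edges.items():
            g.add_edge(a, b, weight=w)
        return g


def validate_labels(labels: Mapping[str, str] | pd.Series) -> pd.Series:
    """Validate a patient → class-label table.

    Requires unique patients, at least two distinct labels, and at least two
    members per class. Returns a string Series named ``label``.
    """
    if not isinstance(labels, pd.Series):
        labels = pd.Series(dict(labels))
    if labels.index.duplicated().any():
        dups = labels.index[labels.index.duplicated()].tolist()
        raise ValueError(f"duplicate patients in label table: {dups}")
    labels = labels.astype(str)
    labels.index = labels.index.astype(str)
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError("label table must contain at least two classes")
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"classes with fewer than two members: {list(small.index)}")
    labels.name = "label"
    return labels
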
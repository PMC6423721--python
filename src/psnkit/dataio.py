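"""Readers and writers for all external representations.

Formats are deliberately plain text: tab-separated patient-by-variable
tables, a two-column patient → class label table, Broad-dialect GMT gene
sets, and three-column edge lists for similarity networks (optionally
GraphML for external viewers). Sparsified networks are sparse by
construction, so edge lists (not adjacency matrices) are the persistence
format.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .containers import GeneSetCollection, PatientDataLayer, SimilarityNetwork, edge_key, validate_labels

__all__ = [
    "MISSING_TOKENS",
    "read_data_layer",
    "write_data_layer",
    "read_labels",
    "write_labels",
    "read_gmt",
    "write_gmt",
    "read_network",
    "write_network",
    "write_graphml",
]

#: cell values parsed as missing; empty string and "NA" cover common dialects
MISSING_TOKENS: tuple[str, ...] = ("", "NA")


def read_data_layer(
    path: str | Path,
    layer_name: str,
    missing_tokens: Sequence[str] = MISSING_TOKENS,
) -> PatientDataLayer:
    """Read a tab-delimited patient-by-variable table.

    First column holds patient IDs, the header row variable names. Cells
    matching ``missing_tokens`` are recorded as missing; any other
    non-numeric cell raises an error naming its row and column.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    raw.index = raw.index.astype(str)
    if raw.index.duplicated().any():
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate patient IDs {dups}")
    if raw.columns.duplicated().any():
        dups = raw.columns[raw.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate variable names {dups}")
    is_missing = raw.isin(list(missing_tokens))
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~is_missing
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value {raw.iat[r, c]!r} at patient "
            f"{raw.index[r]!r}, variable {raw.columns[c]!r}"
        )
    return PatientDataLayer(layer_name, numeric.mask(is_missing))


def write_data_layer(layer: PatientDataLayer, path: str | Path) -> Path:
    path = Path(path)
    df = layer.data.copy()
    df.index.name = "patient"
    df.to_csv(path, sep="\t", na_rep="NA")
    return path


def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column (patient, label) tab-delimited table with header."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (patient, label)")
    series = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values)
    return validate_labels(series)


def write_labels(labels: pd.Series, path: str | Path) -> Path:
    path = Path(path)
    out = validate_labels(labels)
    pd.DataFrame({"patient": out.index, "label": out.values}).to_csv(
        path, sep="\t", index=False
    )
    return path


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a Broad-dialect GMT file: name TAB description TAB member...

    Member lists are de-duplicated preserving order; sets with no members
    after removing empty tokens are dropped with a warning. Duplicate set
    names are an error.
    """
    sets: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            name, desc, *members = fields
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            seen: dict[str, None] = {}
            for m in members:
                if m:
                    seen.setdefault(m, None)
            if not seen:
                warnings.warn(f"{path}:{lineno}: gene set {name!r} is empty, dropped")
                continue
            sets[name] = tuple(seen)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(sets: GeneSetCollection, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, members in sets:
            desc = sets.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")
    return path


NETWORK_HEADER = "patientA\tpatientB\tweight"


def write_network(net: SimilarityNetwork, path: str | Path) -> Path:
    """Write a three-column edge list with one-line header.

    Each undirected edge is written once with endpoints in lexicographic
    order; weights are printed to six decimal places.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(NETWORK_HEADER + "\n")
        for (a, b) in sorted(net.edges):
            fh.write(f"{a}\t{b}\t{net.edges[(a, b)]:.6f}\n")
    return path


def read_network(
    path: str | Path,
    name: str | None = None,
    metric: str = "",
    nodes: Iterable[str] | None = None,
) -> SimilarityNetwork:
    """Read a three-column edge list written by :func:`write_network`.

    The node set defaults to the union of edge endpoints (isolated nodes
    are not representable in an edge list; pass ``nodes`` to restore them).
    """
    path = Path(path)
    edges: dict[tuple[str, str], float] = {}
    endpoints: dict[str, None] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ValueError(f"{path}: empty file")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            a, b, w = fields
            key = edge_key(a, b)
            if key in edges:
                raise ValueError(f"{path}:{lineno}: duplicate edge {key}")
            edges[key] = float(w)
            endpoints.setdefault(a, None)
            endpoints.setdefault(b, None)
    node_tuple = tuple(nodes) if nodes is not None else tuple(sorted(endpoints))
    return SimilarityNetwork(name or path.stem, node_tuple, edges, metric)


def write_graphml(net: SimilarityNetwork, path: str | Path) -> Path:
    import networkx as nx

    path = Path(path)
    nx.write_graphml(net.to_networkx(), path)
    return path
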
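"""Integrated-network reporting: class separation and display export.

The integrated patient network is the uniform average of the
consistently top-scoring feature networks. Similarity (in [0, 1]) is
converted to dissimilarity d = 1 - w, weighted shortest paths are computed
with Dijkstra's method, and a one-tailed Wilcoxon-Mann-Whitney test asks
whether within-class path distances are collectively shorter than
across-class distances. Display filters reproduce the conventions used for
network figures (top-distance filtering, or a weight floor plus per-node
top-fraction rule).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .containers import SimilarityNetwork, edge_key, validate_labels
from .dataio import write_network
from .integration import combine_networks
from .scoring import FeatureScoreTable

__all__ = [
    "SeparationStats",
    "integrate_top_features",
    "to_dissimilarity",
    "class_separation",
    "export_display_network",
    "filter_display_network",
]

#: combined pair count at or below which the exact WMW null is used
EXACT_WMW_MAX_PAIRS = 20


@dataclass
class SeparationStats:
    """Shortest-path class separation on the integrated network."""

    within_class_mean_distance: float
    between_class_mean_distance: float
    wmw_p: float
    n_within_pairs: int
    n_between_pairs: int
    n_unreachable_pairs: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def integrate_top_features(
    per_split_scores: Sequence[FeatureScoreTable],
    nets: Sequence[SimilarityNetwork],
    criterion: str = "max-in-all-splits",
    min_fraction: float = 0.7,
    score_floor: int | None = None,
) -> SimilarityNetwork:
    """Uniform average of the networks passing a cross-split score criterion.

    ``max-in-all-splits`` keeps features attaining the maximum possible
    score in every split for at least one class; ``floor`` keeps features
    whose cross-split consistency reaches ``score_floor`` in at least
    ``min_fraction`` of splits.
    """
    from .scoring import consistency_across_splits

    summary = consistency_across_splits(per_split_scores, min_fraction, score_floor)
    if criterion == "max-in-all-splits":
        passing = set(summary.loc[summary["max_in_all_splits"], "feature"])
    elif criterion == "floor":
        if score_floor is None:
            raise ValueError("criterion 'floor' requires score_floor")
        passing = set(summary.loc[summary["passes_floor"], "feature"])
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    chosen = [n for n in nets if n.name in passing]
    if not chosen:
        raise ValueError(
            "no feature passes the integration criterion; relax the criterion "
            "(e.g. use 'floor' with a lower score_floor)"
        )
    return combine_networks(chosen, name="integrated")


def to_dissimilarity(net: SimilarityNetwork) -> SimilarityNetwork:
    """Convert unit-interval similarities to distances d = 1 - w.

    Absent edges stay absent (they do not become distance 1).
    """
    for key, w in net.edges.items():
        if not (0.0 <= w <= 1.0):
            raise ValueError(f"edge {key} weight {w} outside [0, 1]")
    edges = {k: 1.0 - w for k, w in net.edges.items()}
    return SimilarityNetwork(net.name, net.nodes, edges, "dissimilarity")


def class_separation(
    net: SimilarityNetwork, labels: Mapping[str, str] | pd.Series
) -> SeparationStats:
    """Within- vs between-class mean shortest-path distance with a WMW test.

    Distances are Dijkstra shortest paths on the 1 - similarity graph,
    taken over unordered pairs of labeled nodes; unreachable pairs are
    excluded from the means and counted. The one-tailed test asks whether
    within-class distances are shorter (exact null for a combined pair
    count up to 20, tie-corrected normal approximation beyond).
    """
    labels = validate_labels(labels)
    nodes = [n for n in net.nodes if n in labels.index]
    present = labels.loc[nodes]
    if present.nunique() < 2:
        raise ValueError("need nodes from at least two classes")
    dist_net = to_dissimilarity(net)
    g = nx.Graph()
    g.add_nodes_from(dist_net.nodes)
    for (a, b), d in dist_net.edges.items():
        g.add_edge(a, b, dist=d)
    lengths = dict(nx.all_pairs_dijkstra_path_length(g, weight="dist"))
    within: list[float] = []
    between: list[float] = []
    unreachable = 0
    for i, a in enumerate(nodes):
        row = lengths.get(a, {})
        for b in nodes[i + 1 :]:
            if b not in row:
                unreachable += 1
                continue
            (within if present[a] == present[b] else between).append(row[b])
    if not within or not between:
        raise ValueError("all pairs unreachable in at least one pair category")
    method = "exact" if len(within) + len(between) <= EXACT_WMW_MAX_PAIRS else "asymptotic"
    p = float(mannwhitneyu(within, between, alternative="less", method=method).pvalue)
    return SeparationStats(
        within_class_mean_distance=float(np.mean(within)),
        between_class_mean_distance=float(np.mean(between)),
        wmw_p=p,
        n_within_pairs=len(within),
        n_between_pairs=len(between),
        n_unreachable_pairs=unreachable,
    )


def filter_display_network(
    net: SimilarityNetwork,
    mode: str = "distance-top",
    distance_fraction: float = 0.4,
    weight_floor: float = 0.7,
    per_node_fraction: float = 0.2,
) -> SimilarityNetwork:
    """Apply a display filter and return the reduced network.

    ``distance-top`` keeps the shortest ``distance_fraction`` of edge
    distances (1 - w, i.e. the strongest similarities); ``figure`` drops
    edges below ``weight_floor`` and keeps, per node, the strongest
    ``per_node_fraction`` of its surviving edges (endpoint union, ties by
    weight descending then edge ID).
    """
    if mode == "distance-top":
        ordered = sorted(net.edges.items(), key=lambda kv: (1.0 - kv[1], kv[0]))
        k = int(round(distance_fraction * len(ordered)))
        edges = dict(ordered[:k])
    elif mode == "figure":
        surviving = {k: w for k, w in net.edges.items() if w >= weight_floor}
        inc: dict[str, list[tuple[float, str]]] = {n: [] for n in net.nodes}
        for (a, b), w in surviving.items():
            inc[a].append((w, b))
            inc[b].append((w, a))
        keep: set[tuple[str, str]] = set()
        for node, lst in inc.items():
            lst.sort(key=lambda t: (-t[0], t[1]))
            k = int(round(per_node_fraction * len(lst)))
            for w, partner in lst[:k]:
                keep.add(edge_key(node, partner))
        edges = {k: surviving[k] for k in keep}
    else:
        raise ValueError(f"unknown display mode {mode!r}")
    if not edges:
        warnings.warn(f"display filter {mode!r} removed every edge")
    return SimilarityNetwork(net.name, net.nodes, edges, net.metric)


def export_display_network(
    net: SimilarityNetwork,
    out_prefix: str | Path,
    mode: str = "distance-top",
    labels: Mapping[str, str] | pd.Series | None = None,
    **filter_kwargs,
) -> tuple[Path, Path | None]:
    """Write the filtered edge list (and node class attributes, if given)."""
    filtered = filter_display_network(net, mode=mode, **filter_kwargs)
    out_prefix = Path(out_prefix)
    edge_path = out_prefix.with_suffix(".edges.tsv")
    write_network(filtered, edge_path)
    attr_path = None
    if labels is not None:
        labels = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
        attr_path = out_prefix.with_suffix(".nodes.tsv")
        rows = [
            {"patient": n, "class": labels.get(n, "")} for n in sorted(filtered.nodes)
        ]
        pd.DataFrame(rows).to_csv(attr_path, sep="\t", index=False)
    return edge_path, attr_path
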
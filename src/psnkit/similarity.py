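"""Patient similarity metrics, per-feature network construction, sparsification.

Metric choice follows the variable-count rule used for data-type level
features: Pearson correlation across variables when a layer has six or more
measures, and the average normalized similarity

    S(a, b, G) = 1 - |a - b| / (max(G) - min(G))

(averaged over variables, S') when it has five or fewer. Pathway features
correlate the expression sub-vectors of a gene set's members. An optional
locally scaled exponential kernel w = exp(-d^2 / (mu * eps)) supports
Euclidean- and correlation-distance variants.

Sparsification prunes each network by a weight cutoff, a per-node top-X
rule (an edge survives if it ranks within the top X of either endpoint),
and an optional global edge cap; patients orphaned by the cap are
re-attached through their single strongest original edge, raised to the
cutoff when weaker.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .containers import GeneSetCollection, PatientDataLayer, SimilarityNetwork, edge_key

logger = logging.getLogger(__name__)

__all__ = [
    "DegenerateVariableError",
    "SparsifierConfig",
    "KernelConfig",
    "normalized_similarity",
    "mean_normalized_similarity",
    "pearson_similarity",
    "scaled_exponential_similarity",
    "build_datatype_network",
    "build_variable_networks",
    "build_pathway_networks",
    "build_kernel_network",
    "sparsify",
    "PEARSON_MIN_VARIABLES",
]

#: layers with at least this many variables use Pearson correlation
PEARSON_MIN_VARIABLES = 6

#: minimum pairwise-complete observations for a Pearson edge
MIN_PEARSON_PAIRS = 3


class DegenerateVariableError(ValueError):
    """Raised when a variable has zero range (max == min)."""


@dataclass
class SparsifierConfig:
    """Pruning parameters: weight ``cutoff``, per-node ``top_x``, global ``max_edges``.

    The default cutoff of 0.3 matches the convention for correlation-based
    networks; exponentially scaled networks use the smallest positive
    representable weight instead (every kernel weight is positive, so only
    the top-X and cap rules bind there).
    """

    cutoff: float = 0.3
    top_x: int = 50
    max_edges: int | None = None

    def __post_init__(self) -> None:
        if self.cutoff < 0:
            raise ValueError("cutoff must be >= 0")
        if self.top_x < 1:
            raise ValueError("top_x must be >= 1")

    @classmethod
    def for_exponential(cls, top_x: int = 50, max_edges: int | None = None) -> "SparsifierConfig":
        return cls(cutoff=np.finfo(float).tiny, top_x=top_x, max_edges=max_edges)


@dataclass
class KernelConfig:
    """Local exponential scaling parameters.

    ``mu`` scales the bandwidth; ``k_neighbors`` sets the neighborhood used
    for each patient's local bandwidth (the mean distance to its k nearest
    neighbors).
    """

    mu: float = 0.5
    k_neighbors: int = 20

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be > 0")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


def normalized_similarity(a: float, b: float, value_range: tuple[float, float]) -> float:
    """Unit-interval similarity of two scalars given the variable's range."""
    vmin, vmax = value_range
    if not vmax > vmin:
        raise DegenerateVariableError(f"degenerate range ({vmin}, {vmax})")
    s = 1.0 - abs(a - b) / (vmax - vmin)
    return float(min(1.0, max(0.0, s)))


def mean_normalized_similarity(
    profile_a: Sequence[float],
    profile_b: Sequence[float],
    ranges: Sequence[tuple[float, float]],
) -> float:
    """Average of per-variable normalized similarities over non-degenerate variables."""
    if not (len(profile_a) == len(profile_b) == len(ranges)):
        raise ValueError("profiles and ranges must have equal length")
    if len(ranges) > 5:
        warnings.warn(
            f"mean normalized similarity over {len(ranges)} variables; "
            "Pearson correlation is the usual choice beyond five"
        )
    sims = []
    for a, b, rng in zip(profile_a, profile_b, ranges):
        try:
            sims.append(normalized_similarity(a, b, rng))
        except DegenerateVariableError:
            continue
    if not sims:
        raise DegenerateVariableError("all variables degenerate")
    return float(np.mean(sims))


def pearson_similarity(x: Sequence[float], y: Sequence[float]) -> float | None:
    """Pearson correlation over pairwise-complete observations.

    Returns ``None`` (edge omitted) with fewer than three complete pairs or
    zero variance in either vector over the complete pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    if mask.sum() < MIN_PEARSON_PAIRS:
        return None
    xs, ys = x[mask], y[mask]
    if np.std(xs) == 0 or np.std(ys) == 0:
        return None
    return float(np.corrcoef(xs, ys)[0, 1])


def scaled_exponential_similarity(
    d: float, eps_i: float, eps_j: float, cfg: KernelConfig | None = None
) -> float:
    """Locally scaled exponential kernel w = exp(-d^2 / (mu * eps)).

    ``eps`` is the average of the two patients' local bandwidths.
    """
    cfg = cfg or KernelConfig()
    if d < 0:
        raise ValueError("distance must be >= 0")
    eps = (eps_i + eps_j) / 2.0
    if eps <= 0:
        raise ValueError("average local bandwidth must be > 0")
    return float(np.exp(-(d**2) / (cfg.mu * eps)))


def _network_from_matrix(
    name: str, ids: Sequence[str], W: np.ndarray, metric: str
) -> SimilarityNetwork:
    """Assemble a network from a symmetric weight matrix; NaN entries are omitted."""
    edges: dict[tuple[str, str], float] = {}
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            w = W[i, j]
            if np.isfinite(w):
                edges[edge_key(ids[i], ids[j])] = float(w)
    return SimilarityNetwork(name, tuple(ids), edges, metric)


def _pairwise_pearson(df: pd.DataFrame) -> np.ndarray:
    """Patient-by-patient Pearson matrix over a patients-by-variables frame.

    Uses pairwise-complete observations under missingness (minimum three
    pairs); undefined correlations come back as NaN and are omitted.
    """
    if df.isna().any().any():
        C = df.T.corr(min_periods=MIN_PEARSON_PAIRS).to_numpy()
    else:
        if df.shape[1] < MIN_PEARSON_PAIRS:
            return np.full((df.shape[0],) * 2, np.nan)
        with np.errstate(invalid="ignore", divide="ignore"):
            C = np.corrcoef(df.to_numpy())
    np.fill_diagonal(C, np.nan)
    return C


def _variable_ranges(df: pd.DataFrame) -> pd.DataFrame:
    lo = df.min(axis=0, skipna=True)
    hi = df.max(axis=0, skipna=True)
    return pd.DataFrame({"lo": lo, "hi": hi})


def _mean_normalized_matrix(df: pd.DataFrame, name: str) -> np.ndarray:
    """Vectorized S' matrix: per-pair mean of per-variable normalized similarity.

    Variables with zero range are dropped with a warning; a pair with no
    jointly observed non-degenerate variable gets no edge (NaN).
    """
    ranges = _variable_ranges(df)
    span = (ranges["hi"] - ranges["lo"]).to_numpy()
    keep = np.isfinite(span) & (span > 0)
    if not keep.any():
        raise DegenerateVariableError(f"layer {name!r}: all variables degenerate")
    if (~keep).any():
        dropped = list(df.columns[~keep])
        warnings.warn(f"layer {name!r}: dropping degenerate variables {dropped}")
    X = df.to_numpy()[:, keep]
    span = span[keep]
    n = X.shape[0]
    total = np.zeros((n, n))
    count = np.zeros((n, n))
    for k in range(X.shape[1]):
        col = X[:, k]
        obs = np.isfinite(col)
        s = 1.0 - np.abs(col[:, None] - col[None, :]) / span[k]
        s = np.clip(s, 0.0, 1.0)
        both = obs[:, None] & obs[None, :]
        total[both] += s[both]
        count += both
    with np.errstate(invalid="ignore"):
        W = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return W


def build_datatype_network(
    layer: PatientDataLayer, metric: str | None = None
) -> SimilarityNetwork:
    """One network for a whole data layer, metric auto-selected by variable count.

    Layers with >= 6 variables use Pearson correlation; smaller layers use
    the average normalized similarity. Pass ``metric`` ("pearson" or
    "normalized") to override.
    """
    if layer.n_patients < 2:
        raise ValueError(f"layer {layer.name!r}: need at least two patients")
    if metric is None:
        metric = "pearson" if layer.n_variables >= PEARSON_MIN_VARIABLES else "normalized"
    if metric == "pearson":
        W = _pairwise_pearson(layer.data)
    elif metric == "normalized":
        W = _mean_normalized_matrix(layer.data, layer.name)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return _network_from_matrix(layer.name, layer.patient_ids, W, metric)


def build_variable_networks(layer: PatientDataLayer) -> list[SimilarityNetwork]:
    """One normalized-similarity network per variable, named ``layer:variable``."""
    nets = []
    for var in layer.variable_ids:
        sub = layer.data[[var]]
        try:
            W = _mean_normalized_matrix(sub, f"{layer.name}:{var}")
        except DegenerateVariableError:
            warnings.warn(f"layer {layer.name!r}: variable {var!r} degenerate, skipped")
            continue
        nets.append(
            _network_from_matrix(f"{layer.name}:{var}", layer.patient_ids, W, "normalized")
        )
    return nets


def build_pathway_networks(
    expr: PatientDataLayer,
    sets: GeneSetCollection,
    size_bounds: tuple[int, int] = (10, 200),
) -> list[SimilarityNetwork]:
    """Per-pathway Pearson similarity over each set's member-gene sub-vectors.

    Sets whose membership (after intersecting with the expression matrix)
    falls outside ``size_bounds`` are skipped and logged.
    """
    lo, hi = size_bounds
    present = set(expr.variable_ids)
    nets: list[SimilarityNetwork] = []
    for name, members in sets:
        genes = [g for g in members if g in present]
        if not genes:
            warnings.warn(f"gene set {name!r}: no member genes in matrix, skipped")
            continue
        if not (lo <= len(genes) <= hi):
            logger.info(
                "gene set %r: %d genes present, outside [%d, %d], skipped",
                name, len(genes), lo, hi,
            )
            continue
        W = _pairwise_pearson(expr.data[genes])
        nets.append(_network_from_matrix(name, expr.patient_ids, W, "pearson"))
    if not nets:
        raise ValueError("no gene set survives the size filter")
    return nets


def build_kernel_network(
    layer: PatientDataLayer,
    mode: str = "euclidean",
    cfg: KernelConfig | None = None,
) -> SimilarityNetwork:
    """Locally scaled exponential-kernel network (Euclidean or Pearson distance).

    Pairwise distance is the Euclidean distance between patient profiles, or
    1 - r for the Pearson variant. Each patient's local bandwidth is the
    mean distance to its k nearest neighbors; a pair's bandwidth averages
    the two local bandwidths with the pair distance itself.
    """
    cfg = cfg or KernelConfig()
    if layer.data.isna().any().any():
        raise ValueError(f"layer {layer.name!r}: impute missing values before kernel scaling")
    n = layer.n_patients
    if cfg.k_neighbors >= n:
        raise ValueError("k_neighbors must be < number of patients")
    if mode == "euclidean":
        D = squareform(pdist(layer.data.to_numpy()))
    elif mode == "pearson":
        C = _pairwise_pearson(layer.data)
        np.fill_diagonal(C, 1.0)
        D = 1.0 - C
    else:
        raise ValueError(f"unknown kernel mode {mode!r}")
    # local bandwidth: mean distance to the k nearest neighbors (self excluded)
    sorted_d = np.sort(D + np.diag(np.full(n, np.inf)), axis=1)
    eps_local = sorted_d[:, : cfg.k_neighbors].mean(axis=1)
    eps = (eps_local[:, None] + eps_local[None, :] + D) / 3.0
    if np.any(eps <= 0):
        eps = np.maximum(eps, np.finfo(float).tiny)
    W = np.exp(-(D**2) / (cfg.mu * eps))
    np.fill_diagonal(W, np.nan)
    return _network_from_matrix(layer.name, layer.patient_ids, W, f"{mode}-expscale")


def sparsify(net: SimilarityNetwork, cfg: SparsifierConfig) -> SimilarityNetwork:
    """Prune a network by cutoff, per-node top-X, and an optional edge cap.

    Steps: (1) drop edges below ``cutoff``; (2) keep an edge if it is among
    the ``top_x`` strongest of either endpoint (ties by weight descending,
    partner ID ascending); (3) with ``max_edges`` set, keep the globally
    strongest ``max_edges`` edges and re-attach every patient left edge-free
    via its single strongest original edge, raising the weight to the cutoff
    if below it.
    """
    if cfg.max_edges is not None and cfg.max_edges < net.n_nodes:
        raise ValueError("max_edges must be >= number of nodes")
    e1 = {k: w for k, w in net.edges.items() if w >= cfg.cutoff}

    inc: dict[str, list[tuple[float, str]]] = {n: [] for n in net.nodes}
    for (a, b), w in e1.items():
        inc[a].append((w, b))
        inc[b].append((w, a))
    keep: set[tuple[str, str]] = set()
    for node, lst in inc.items():
        lst.sort(key=lambda t: (-t[0], t[1]))
        for w, partner in lst[: cfg.top_x]:
            keep.add(edge_key(node, partner))
    e2 = {k: e1[k] for k in keep}

    if cfg.max_edges is None:
        return SimilarityNetwork(net.name, net.nodes, e2, net.metric)

    ordered = sorted(e2.items(), key=lambda kv: (-kv[1], kv[0]))
    e3 = dict(ordered[: cfg.max_edges])

    deg = {n: 0 for n in net.nodes}
    for a, b in e3:
        deg[a] += 1
        deg[b] += 1
    original_inc = net.incident()
    for node in sorted(net.nodes):
        if deg[node] > 0 or not original_inc[node]:
            continue
        w, partner = min(original_inc[node], key=lambda t: (-t[0], t[1]))
        key = edge_key(node, partner)
        e3[key] = max(w, cfg.cutoff)
        deg[node] += 1
        deg[partner] += 1
    return SimilarityNetwork(net.name, net.nodes, e3, net.metric)
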
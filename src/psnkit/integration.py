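"""Network weighting, combination, and query-driven label propagation.

This is the recommender-style core: given a set of patient similarity
networks and a query (the known members of a class), fit non-negative
per-network weights by regularized regression of each network's
off-diagonal adjacency entries onto a label-derived target, combine
networks into one association network, and rank all patients by smoothing
a label bias vector over that network.

The regression target for an unordered patient pair (i, j) is t_ij =
u_i * u_j where u is the zero-mean label vector (u_i = n_o/n for query
members, -n_q/n otherwise): same-group pairs get positive target values and
cross-group pairs negative ones, so a network enriched for within-class
edges earns a positive weight. Non-negativity is enforced by dropping
features with non-positive fitted weight and re-solving.

Label propagation solves f = (I + lam * L_sym)^{-1} y with L_sym the
symmetric-normalized graph Laplacian; isolated nodes keep f_i = y_i.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .containers import SimilarityNetwork

__all__ = [
    "QuerySpec",
    "NetworkWeights",
    "PropagationResult",
    "ConvergenceError",
    "label_bias",
    "fit_network_weights",
    "combine_networks",
    "propagate_labels",
    "iterative_propagate",
]


class ConvergenceError(RuntimeError):
    """Iterative solver failed to reach the requested tolerance."""


@dataclass(frozen=True)
class QuerySpec:
    """A query (the '+' patients) within a patient universe."""

    query_ids: tuple[str, ...]
    universe_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "query_ids", tuple(self.query_ids))
        object.__setattr__(self, "universe_ids", tuple(self.universe_ids))
        uni = set(self.universe_ids)
        qry = set(self.query_ids)
        if len(uni) != len(self.universe_ids):
            raise ValueError("duplicate IDs in universe")
        if len(qry) != len(self.query_ids):
            raise ValueError("duplicate IDs in query")
        if not qry <= uni:
            raise ValueError("query must be a subset of the universe")
        if len(qry) < 2:
            raise ValueError("query needs at least two patients")
        if len(uni - qry) < 1:
            raise ValueError("universe must contain at least one non-query patient")

    @property
    def n_query(self) -> int:
        return len(self.query_ids)

    @property
    def n_other(self) -> int:
        return len(self.universe_ids) - len(self.query_ids)


@dataclass
class NetworkWeights:
    """Fitted non-negative network weights; dropped features had weight <= 0."""

    weights: dict[str, float]
    intercept: float
    ridge_lambda: float
    dropped: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("reported weights must be strictly positive")
        if set(self.weights) & set(self.dropped):
            raise ValueError("a feature cannot be both reported and dropped")


@dataclass
class PropagationResult:
    """Per-patient propagation scores and deterministic ranks for one query."""

    nodes: tuple[str, ...]
    scores: np.ndarray
    bias: np.ndarray
    ranks: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        order = sorted(range(len(self.nodes)), key=lambda i: (-self.scores[i], self.nodes[i]))
        self.ranks = {self.nodes[i]: r + 1 for r, i in enumerate(order)}

    def score_of(self, node: str) -> float:
        return float(self.scores[self.nodes.index(node)])

    def normalized_ranks(self) -> dict[str, float]:
        """Rank rescaled to [0, 1] with 1 = most query-like."""
        n = len(self.nodes)
        if n == 1:
            return {self.nodes[0]: 1.0}
        return {node: 1.0 - (r - 1) / (n - 1) for node, r in self.ranks.items()}


def label_bias(q: QuerySpec) -> np.ndarray:
    """Bias vector y: +1 for query patients, (n_q - n_o)/(n_q + n_o) for the rest."""
    b = (q.n_query - q.n_other) / (q.n_query + q.n_other)
    qset = set(q.query_ids)
    return np.array([1.0 if p in qset else b for p in q.universe_ids])


def _pair_design(
    nets: Sequence[SimilarityNetwork],
    q: QuerySpec,
    include_nonquery_pairs: bool,
) -> tuple[np.ndarray, np.ndarray]:
    universe = list(q.universe_ids)
    n = len(universe)
    qmask = np.array([p in set(q.query_ids) for p in universe])
    u = np.where(qmask, q.n_other / n, -q.n_query / n)
    iu, ju = np.triu_indices(n, k=1)
    if not include_nonquery_pairs:
        sel = qmask[iu] | qmask[ju]
        iu, ju = iu[sel], ju[sel]
    t = u[iu] * u[ju]
    X = np.empty((len(iu), len(nets)))
    for k, net in enumerate(nets):
        A = net.to_adjacency(universe)
        X[:, k] = A[iu, ju]
    return X, t


def _ridge_solve(X: np.ndarray, t: np.ndarray, lam: float) -> np.ndarray:
    """Minimize ||t - b0 - X b||^2 + lam * ||b||^2 (intercept unpenalized).

    Solved as an augmented least-squares problem; at lam = 0 this reduces to
    the minimum-norm ordinary least-squares solution, which keeps the fit
    well defined for collinear (e.g. duplicated) networks.
    """
    m, p = X.shape
    top = np.hstack([np.ones((m, 1)), X])
    if lam > 0:
        reg = np.hstack([np.zeros((p, 1)), np.sqrt(lam) * np.eye(p)])
        aug = np.vstack([top, reg])
        rhs = np.concatenate([t, np.zeros(p)])
    else:
        aug, rhs = top, t
    beta, *_ = np.linalg.lstsq(aug, rhs, rcond=None)
    return beta


def fit_network_weights(
    nets: Sequence[SimilarityNetwork],
    q: QuerySpec,
    ridge_lambda: float = 1.0,
    include_nonquery_pairs: bool = True,
) -> NetworkWeights:
    """Fit non-negative network weights against the label-derived pair target.

    Features whose fitted coefficient is non-positive are dropped and the
    system re-solved until every remaining coefficient is positive (the set
    shrinks strictly, so the loop terminates). An empty result (no network
    with positive weight) is signalled by an empty ``weights`` dict, not an
    exception — the feature simply scores zero for that round.
    """
    if ridge_lambda < 0:
        raise ValueError("ridge_lambda must be >= 0")
    names = [net.name for net in nets]
    if len(set(names)) != len(names):
        raise ValueError("duplicate network names")
    X, t = _pair_design(nets, q, include_nonquery_pairs)
    active = list(range(len(nets)))
    dropped: list[str] = []
    intercept = float(np.mean(t)) if len(t) else 0.0
    while active:
        beta = _ridge_solve(X[:, active], t, ridge_lambda)
        intercept = float(beta[0])
        coef = beta[1:]
        neg = [active[k] for k in range(len(active)) if coef[k] <= 0]
        if not neg:
            weights = {names[a]: float(coef[k]) for k, a in enumerate(active)}
            return NetworkWeights(weights, intercept, ridge_lambda, tuple(dropped))
        dropped.extend(names[a] for a in neg)
        active = [a for a in active if a not in set(neg)]
    return NetworkWeights({}, intercept, ridge_lambda, tuple(dropped))


def combine_networks(
    nets: Sequence[SimilarityNetwork],
    weights: NetworkWeights | Mapping[str, float] | None = None,
    name: str = "integrated",
) -> SimilarityNetwork:
    """Weighted (or uniform-average) combination of networks.

    Edge weight = sum(alpha_i * w_i(a, b)) / sum(alpha_i); a network without
    the edge contributes zero to the numerator, so uniform averaging keeps
    the output in [0, 1] when the inputs are.
    """
    if weights is not None and not isinstance(weights, Mapping):
        weights = weights.weights
    if weights is not None:
        nets = [n for n in nets if weights.get(n.name, 0.0) > 0]
    if not nets:
        raise ValueError("no networks (with positive weight) to combine")
    alphas = [1.0 if weights is None else float(weights[n.name]) for n in nets]
    total = float(sum(alphas))
    nodes: dict[str, None] = {}
    for net in nets:
        for node in net.nodes:
            nodes.setdefault(node, None)
    acc: dict[tuple[str, str], float] = {}
    for alpha, net in zip(alphas, nets):
        for key, w in net.edges.items():
            acc[key] = acc.get(key, 0.0) + alpha * w
    edges = {k: v / total for k, v in acc.items()}
    return SimilarityNetwork(name, tuple(nodes), edges, "combined")


def _bias_array(W: SimilarityNetwork, y: Mapping[str, float] | np.ndarray) -> np.ndarray:
    if isinstance(y, Mapping):
        missing = [n for n in W.nodes if n not in y]
        if missing:
            raise ValueError(f"bias undefined for nodes {missing[:5]}")
        return np.array([float(y[n]) for n in W.nodes])
    y = np.asarray(y, dtype=float)
    if y.shape != (W.n_nodes,):
        raise ValueError("bias vector length must match the network's node count")
    return y


def _laplacian(W: SimilarityNetwork) -> sp.csr_matrix:
    """Symmetric-normalized Laplacian; isolated nodes get an all-zero row."""
    A = sp.csr_matrix(W.to_adjacency())
    if A.nnz and not np.all(np.isfinite(A.data)):
        raise ValueError("non-finite edge weights")
    deg = np.asarray(A.sum(axis=1)).ravel()
    with np.errstate(divide="ignore"):
        dinv = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
    Dinv = sp.diags(dinv)
    S = Dinv @ A @ Dinv
    I_conn = sp.diags((deg > 0).astype(float))
    return (I_conn - S).tocsr()


def propagate_labels(
    W: SimilarityNetwork,
    y: Mapping[str, float] | np.ndarray,
    prop_lambda: float = 1.0,
) -> PropagationResult:
    """Closed-form label propagation f = (I + lam * L_sym)^{-1} y.

    The system is positive definite for lam > 0, so a direct dense solve is
    exact; isolated nodes satisfy f_i = y_i. Ranks order patients by
    descending score with ties broken by ascending patient ID.
    """
    if prop_lambda <= 0:
        raise ValueError("prop_lambda must be > 0")
    yv = _bias_array(W, y)
    L = _laplacian(W).toarray()
    M = np.eye(W.n_nodes) + prop_lambda * L
    f = np.linalg.solve(M, yv)
    return PropagationResult(tuple(W.nodes), f, yv)


def iterative_propagate(
    W: SimilarityNetwork,
    y: Mapping[str, float] | np.ndarray,
    prop_lambda: float = 1.0,
    tol: float = 1e-10,
    maxiter: int | None = None,
) -> PropagationResult:
    """Conjugate-gradient label propagation matching the closed form within ``tol``.

    All eigenvalues of I + lam * L_sym are >= 1, so a residual 2-norm below
    ``tol`` bounds the max-norm error against the direct solve by ``tol``.
    """
    if prop_lambda <= 0:
        raise ValueError("prop_lambda must be > 0")
    if tol <= 0:
        raise ValueError("tol must be > 0")
    yv = _bias_array(W, y)
    n = W.n_nodes
    M = (sp.identity(n, format="csr") + prop_lambda * _laplacian(W)).tocsr()
    f, info = spla.cg(M, yv, rtol=0.0, atol=tol / 2.0, maxiter=maxiter or 20 * max(n, 10))
    residual = float(np.linalg.norm(M @ f - yv))
    if info != 0 or residual > tol:
        raise ConvergenceError(
            f"conjugate gradient did not reach tol={tol:g} (residual {residual:.3e})"
        )
    return PropagationResult(tuple(W.nodes), f, yv)
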
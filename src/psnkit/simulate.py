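"""Synthetic two-class cohorts with known ground truth.

The generator emulates a gene-expression cohort in which a chosen subset of
pathways carries a class effect: baseline expression is standard normal and
every gene of a predictive set is shifted in the "case" class by a
gene-specific offset of magnitude ``effect_size`` with alternating sign.
Alternating signs matter: a constant shift across a pathway's member genes
would be removed by the per-patient centering inside Pearson correlation,
whereas sign-varying shifts create a shared expression profile among cases
that pathway-level similarity detects. Optional clinical variables carry
stated mean shifts (or pure noise), and missingness is completely at
random.

``make_fixture`` provides the small hand-checkable instances used across
the test-suite: the six-patient two-clique networks, the four-node
class-separation instance, and the standard separable / null cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import GeneSetCollection, PatientDataLayer, SimilarityNetwork, validate_labels
from .integration import QuerySpec

__all__ = ["SimulationSpec", "simulate_cohort", "make_fixture", "FIXTURE_NAMES"]


@dataclass
class SimulationSpec:
    """Parameters of the synthetic two-class cohort.

    Defaults describe the standard study cohort used throughout the tests:
    60 patients per class, 30 disjoint 20-gene sets of which 3 are
    predictive with a standardized per-gene effect magnitude of 1.5.
    """

    n_per_class: int = 60
    n_genes: int = 600
    n_sets: int = 30
    set_size: tuple[int, int] = (20, 20)
    n_predictive_sets: int = 3
    effect_size: float = 1.5
    n_clinical_vars: int = 0
    clinical_effects: Sequence[float] | None = None
    missing_rate: float = 0.0
    overlap_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_predictive_sets > self.n_sets:
            raise ValueError("n_predictive_sets cannot exceed n_sets")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if not (0 <= self.overlap_fraction < 1):
            raise ValueError("overlap_fraction must be in [0, 1)")


def simulate_cohort(
    spec: SimulationSpec,
) -> tuple[PatientDataLayer, PatientDataLayer | None, pd.Series, GeneSetCollection, dict]:
    """Generate (expression, clinical-or-None, labels, gene sets, truth record).

    Fully deterministic for a given spec (including seed). The truth record
    lists the predictive set names, the shifted class, and the per-gene
    offsets actually applied.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.set_size
    sizes = rng.integers(lo, hi + 1, size=spec.n_sets)
    unique_needed = int(sizes.sum() - np.floor(spec.overlap_fraction * sizes[1:].sum()))
    if spec.n_genes < unique_needed:
        raise ValueError(
            f"n_genes={spec.n_genes} too small for {spec.n_sets} sets "
            f"needing {unique_needed} distinct genes"
        )
    width = len(str(spec.n_genes))
    genes = [f"g{i + 1:0{width}d}" for i in range(spec.n_genes)]
    sets: dict[str, tuple[str, ...]] = {}
    cursor = 0
    used: list[str] = []
    for s, size in enumerate(sizes):
        n_overlap = int(np.floor(spec.overlap_fraction * size)) if s > 0 else 0
        members: list[str] = []
        if n_overlap and used:
            members.extend(
                rng.choice(used, size=min(n_overlap, len(used)), replace=False)
            )
        fresh = genes[cursor : cursor + (int(size) - len(members))]
        cursor += len(fresh)
        members.extend(fresh)
        sets[f"SET{s + 1:03d}"] = tuple(members)
        used.extend(fresh)
    gene_sets = GeneSetCollection(
        sets, {name: "synthetic pathway" for name in sets}
    )

    n = spec.n_per_class
    pad = len(str(n))
    patients = [f"case{i + 1:0{pad}d}" for i in range(n)] + [
        f"control{i + 1:0{pad}d}" for i in range(n)
    ]
    labels = pd.Series(["case"] * n + ["control"] * n, index=patients, name="label")

    expr = rng.standard_normal((2 * n, spec.n_genes))
    predictive = [f"SET{s + 1:03d}" for s in range(spec.n_predictive_sets)]
    gene_index = {g: i for i, g in enumerate(genes)}
    gene_effects: dict[str, float] = {}
    for name in predictive:
        for pos, g in enumerate(sets[name]):
            delta = spec.effect_size * (1.0 if pos % 2 == 0 else -1.0)
            gene_effects[g] = delta
            expr[:n, gene_index[g]] += delta
    if spec.missing_rate > 0:
        mask = rng.random(expr.shape) < spec.missing_rate
        expr = np.where(mask, np.nan, expr)
    expr_layer = PatientDataLayer(
        "expression", pd.DataFrame(expr, index=patients, columns=genes)
    )

    clinical_layer = None
    if spec.n_clinical_vars > 0:
        effects = list(spec.clinical_effects or [])
        effects += [0.0] * (spec.n_clinical_vars - len(effects))
        clin = rng.standard_normal((2 * n, spec.n_clinical_vars))
        for j, eff in enumerate(effects[: spec.n_clinical_vars]):
            clin[:n, j] += eff
        if spec.missing_rate > 0:
            mask = rng.random(clin.shape) < spec.missing_rate
            clin = np.where(mask, np.nan, clin)
        cols = [f"clin{j + 1:02d}" for j in range(spec.n_clinical_vars)]
        clinical_layer = PatientDataLayer(
            "clinical", pd.DataFrame(clin, index=patients, columns=cols)
        )

    truth = {
        "predictive_sets": predictive,
        "shifted_class": "case",
        "effect_size": spec.effect_size,
        "gene_effects": gene_effects,
        "seed": spec.seed,
    }
    return expr_layer, clinical_layer, validate_labels(labels), gene_sets, truth


FIXTURE_NAMES = ("two-cliques-6", "separable-120", "null-120", "wmw-4node")


def _two_cliques_fixture() -> dict:
    """Six patients, query {p1..p3}; three contrast networks.

    Network A joins each within-group trio into a weight-1 clique (the
    informative pattern), network B is the complete bipartite query/other
    graph (the anti-pattern), and network C is the uniform complete graph
    (uninformative, absorbed by the regression intercept).
    """
    patients = tuple(f"p{i}" for i in range(1, 7))
    groups = [patients[:3], patients[3:]]
    edges_a = {}
    for grp in groups:
        for i in range(3):
            for j in range(i + 1, 3):
                edges_a[(grp[i], grp[j])] = 1.0
    edges_b = {(a, b): 1.0 for a in groups[0] for b in groups[1]}
    edges_c = {}
    for i in range(6):
        for j in range(i + 1, 6):
            edges_c[(patients[i], patients[j])] = 1.0
    net_a = SimilarityNetwork("A-cliques", patients, edges_a, "constructed")
    net_b = SimilarityNetwork("B-bipartite", patients, edges_b, "constructed")
    net_c = SimilarityNetwork("C-uniform", patients, edges_c, "constructed")
    return {
        "networks": [net_a, net_b, net_c],
        "query": QuerySpec(groups[0], patients),
        "informative": "A-cliques",
        "anti": "B-bipartite",
        "uniform": "C-uniform",
    }


def _wmw_4node_fixture() -> dict:
    """Two tight same-class pairs with weak cross-class similarity."""
    nodes = ("p1", "p2", "p3", "p4")
    edges = {
        ("p1", "p2"): 0.9,
        ("p3", "p4"): 0.9,
        ("p1", "p3"): 0.1,
        ("p1", "p4"): 0.1,
        ("p2", "p3"): 0.1,
        ("p2", "p4"): 0.1,
    }
    labels = pd.Series({"p1": "A", "p2": "A", "p3": "B", "p4": "B"})
    return {
        "network": SimilarityNetwork("wmw-4node", nodes, edges, "constructed"),
        "labels": validate_labels(labels),
    }


def make_fixture(name: str):
    """Return one of the canonical hand-checkable instances by name."""
    if name == "two-cliques-6":
        return _two_cliques_fixture()
    if name == "wmw-4node":
        return _wmw_4node_fixture()
    if name == "separable-120":
        return simulate_cohort(SimulationSpec(seed=7))
    if name == "null-120":
        return simulate_cohort(SimulationSpec(effect_size=0.0, seed=7))
    raise ValueError(f"unknown fixture {name!r}; choose one of {FIXTURE_NAMES}")
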
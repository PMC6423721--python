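"""Shared fixtures: canonical hand-checkable instances and the standard cohort.

The expensive end-to-end run on the standard separable cohort is computed
once per session and shared by the predictor, reporting, and acceptance
tests.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from psnkit import (
    PredictorConfig,
    SparsifierConfig,
    build_pathway_networks,
    make_fixture,
    run_predictor,
    sparsify,
)
from psnkit.containers import PatientDataLayer, SimilarityNetwork, validate_labels


@pytest.fixture(scope="session")
def two_cliques():
    return make_fixture("two-cliques-6")


@pytest.fixture(scope="session")
def wmw4():
    return make_fixture("wmw-4node")


@pytest.fixture(scope="session")
def cohort():
    """The standard separable cohort: (expression, labels, gene sets, truth)."""
    expr, clinical, labels, sets, truth = make_fixture("separable-120")
    return expr, labels, sets, truth


@pytest.fixture(scope="session")
def cohort_networks(cohort):
    """Sparsified pathway networks over the full standard cohort."""
    expr, labels, sets, truth = cohort
    return [sparsify(n, SparsifierConfig()) for n in build_pathway_networks(expr, sets)]


@pytest.fixture(scope="session")
def cohort_report(cohort):
    """Five-split end-to-end run on the standard cohort (pathway features)."""
    expr, labels, sets, truth = cohort
    cfg = PredictorConfig(n_splits=5, feature_mode="pathway", master_seed=11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_predictor([expr], labels, cfg, sets)


def random_network(
    rng: np.random.Generator,
    n_nodes: int,
    density: float = 0.15,
    name: str = "random",
) -> SimilarityNetwork:
    nodes = tuple(f"n{i:03d}" for i in range(n_nodes))
    edges = {}
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < density:
                edges[(nodes[i], nodes[j])] = float(rng.random())
    return SimilarityNetwork(name, nodes, edges)


def small_layer(values, name="layer", prefix="p") -> PatientDataLayer:
    values = np.asarray(values, dtype=float)
    ids = [f"{prefix}{i + 1}" for i in range(values.shape[0])]
    cols = [f"v{j + 1}" for j in range(values.shape[1])]
    return PatientDataLayer(name, pd.DataFrame(values, index=ids, columns=cols))


def binary_labels(n_a: int, n_b: int, prefix="p") -> pd.Series:
    ids = [f"{prefix}{i + 1}" for i in range(n_a + n_b)]
    return validate_labels(pd.Series(["a"] * n_a + ["b"] * n_b, index=ids))
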
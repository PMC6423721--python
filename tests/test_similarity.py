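"""Similarity metrics, network builders, and the sparsifier."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psnkit import (
    KernelConfig,
    SparsifierConfig,
    build_datatype_network,
    build_kernel_network,
    build_pathway_networks,
    build_variable_networks,
    mean_normalized_similarity,
    normalized_similarity,
    pearson_similarity,
    scaled_exponential_similarity,
    sparsify,
)
from psnkit.containers import GeneSetCollection, PatientDataLayer, SimilarityNetwork
from psnkit.similarity import DegenerateVariableError

from conftest import random_network, small_layer


class TestNormalizedSimilarity:
    @pytest.mark.parametrize(
        "a,b,rng,expected",
        [
            (5, 5, (1, 10), 1.0),       # identical values
            (20, 60, (20, 60), 0.0),    # extremes of the range
            (30, 40, (20, 60), 0.75),   # 1 - 10/40
        ],
    )
    def test_hand_values(self, a, b, rng, expected):
        assert normalized_similarity(a, b, rng) == pytest.approx(expected)

    def test_degenerate_range_raises(self):
        with pytest.raises(DegenerateVariableError):
            normalized_similarity(1, 1, (3, 3))

    @given(
        a=st.floats(0, 10), b=st.floats(0, 10),
        lo=st.floats(-5, 0), hi=st.floats(1, 10),
    )
    @settings(max_examples=50, derandomize=True)
    def test_symmetric_and_bounded(self, a, b, lo, hi):
        s = normalized_similarity(a, b, (lo, hi))
        assert s == normalized_similarity(b, a, (lo, hi))
        assert 0.0 <= s <= 1.0


class TestMeanNormalizedSimilarity:
    def test_average_of_per_variable_similarities(self):
        # variable 1: 1 - 1/2 = 0.5; variable 2: identical -> 1.0
        s = mean_normalized_similarity([1, 0], [2, 0], [(0, 2), (0, 5)])
        assert s == pytest.approx(0.75)

    def test_identical_profiles(self):
        assert mean_normalized_similarity([1, 2, 3], [1, 2, 3], [(0, 4)] * 3) == 1.0

    def test_degenerate_variable_excluded(self):
        # middle variable has zero range; remaining two give 0.5 each
        s = mean_normalized_similarity(
            [1, 5, 0], [2, 5, 2], [(0, 2), (5, 5), (0, 4)]
        )
        assert s == pytest.approx(0.5)

    def test_all_degenerate_raises(self):
        with pytest.raises(DegenerateVariableError):
            mean_normalized_similarity([1], [2], [(3, 3)])


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(5.0)
        assert pearson_similarity(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_similarity(x, -x) == pytest.approx(-1.0)

    def test_hand_value(self):
        assert pearson_similarity([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_undefined_cases_return_none(self):
        assert pearson_similarity([1, 1, 1], [1, 2, 3]) is None  # zero variance
        assert pearson_similarity([1, 2], [1, 2]) is None  # too few pairs
        # missing entries reduce the complete-pair count below the minimum
        assert pearson_similarity([1, np.nan, 3, np.nan], [1, 2, np.nan, 4]) is None

    def test_pairwise_complete(self):
        x = [1, 2, 3, np.nan]
        y = [1, 3, 2, 5]
        assert pearson_similarity(x, y) == pytest.approx(0.5)


class TestExponentialKernel:
    def test_kernel_at_origin(self):
        assert scaled_exponential_similarity(0.0, 1.0, 1.0) == 1.0

    def test_hand_value(self):
        # d^2 = 1, mu = 0.5, mean bandwidth = 2 -> exp(-1)
        s = scaled_exponential_similarity(1.0, 2.0, 2.0, KernelConfig(mu=0.5))
        assert s == pytest.approx(np.exp(-1))

    def test_monotone_in_distance(self):
        cfg = KernelConfig(mu=0.5)
        assert scaled_exponential_similarity(0.5, 1, 1, cfg) > scaled_exponential_similarity(
            0.9, 1, 1, cfg
        )

    def test_zero_bandwidth_raises(self):
        with pytest.raises(ValueError):
            scaled_exponential_similarity(1.0, 0.0, 0.0)

    def test_kernel_network_weights_in_unit_interval(self):
        rng = np.random.default_rng(3)
        layer = small_layer(rng.standard_normal((12, 6)))
        net = build_kernel_network(layer, "euclidean", KernelConfig(mu=0.5, k_neighbors=4))
        ws = np.array(list(net.edges.values()))
        assert net.n_edges == 12 * 11 // 2
        assert np.all((ws > 0) & (ws <= 1))


class TestDatatypeNetwork:
    def test_metric_chosen_by_variable_count(self):
        rng = np.random.default_rng(0)
        wide = small_layer(rng.standard_normal((5, 20)))
        assert build_datatype_network(wide).metric == "pearson"
        narrow = small_layer(rng.standard_normal((5, 3)))
        assert build_datatype_network(narrow).metric == "normalized"
        boundary = small_layer(rng.standard_normal((5, 6)))
        assert build_datatype_network(boundary).metric == "pearson"

    def test_two_patient_layer_single_edge(self):
        layer = small_layer([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        net = build_datatype_network(layer)
        assert net.n_edges == 1

    def test_network_weights_symmetric_in_input_order(self):
        rng = np.random.default_rng(5)
        vals = rng.standard_normal((6, 10))
        layer = small_layer(vals)
        flipped = small_layer(vals[::-1], prefix="p")
        flipped.data.index = layer.patient_ids[::-1]
        n1 = build_datatype_network(layer)
        n2 = build_datatype_network(PatientDataLayer("layer", flipped.data))
        assert {k: pytest.approx(v) for k, v in n1.edges.items()} == n2.edges


class TestVariableNetworks:
    def test_one_network_per_variable(self):
        layer = small_layer([[0.0, 5.0], [1.0, 5.0], [2.0, 7.0]])
        nets = build_variable_networks(layer)
        assert [n.name for n in nets] == ["layer:v1", "layer:v2"]
        # v1 values 0,1,2 with range 2: s(p1,p2) = 0.5
        assert nets[0].weight("p1", "p2") == pytest.approx(0.5)


class TestPathwayNetworks:
    @pytest.fixture()
    def expr_and_sets(self):
        rng = np.random.default_rng(11)
        genes = [f"G{i}" for i in range(40)]
        df = pd.DataFrame(
            rng.standard_normal((10, 40)),
            index=[f"p{i}" for i in range(10)],
            columns=genes,
        )
        sets = GeneSetCollection(
            {
                "BIG": tuple(genes[:15]),
                "SMALL": tuple(genes[15:20]),       # 5 genes, below bounds
                "ABSENT": ("X1", "X2", "X3"),       # nothing in the matrix
                "OTHER": tuple(genes[20:32]),
            }
        )
        return PatientDataLayer("expression", df), sets

    def test_size_filter_and_membership(self, expr_and_sets):
        expr, sets = expr_and_sets
        with pytest.warns(UserWarning, match="ABSENT"):
            nets = build_pathway_networks(expr, sets, (10, 200))
        assert sorted(n.name for n in nets) == ["BIG", "OTHER"]

    def test_matches_dense_correlation_oracle(self, expr_and_sets):
        """Pathway edges equal dense pairwise correlation over member genes."""
        expr, sets = expr_and_sets
        with pytest.warns(UserWarning):
            nets = build_pathway_networks(expr, sets, (10, 200))
        net = {n.name: n for n in nets}["BIG"]
        sub = expr.data[list(sets.sets["BIG"])].to_numpy()
        oracle = np.corrcoef(sub)
        ids = expr.patient_ids
        for i in range(10):
            for j in range(i + 1, 10):
                assert net.weight(ids[i], ids[j]) == pytest.approx(oracle[i, j], abs=1e-12)

    def test_no_survivor_raises(self, expr_and_sets):
        expr, sets = expr_and_sets
        with pytest.raises(ValueError, match="no gene set"), pytest.warns(UserWarning):
            build_pathway_networks(expr, sets, (100, 200))


class TestSparsify:
    def test_cutoff_removes_weak_edges(self):
        net = SimilarityNetwork(
            "n", ("a", "b", "c"), {("a", "b"): 0.2, ("a", "c"): 0.5, ("b", "c"): 0.3}
        )
        out = sparsify(net, SparsifierConfig(cutoff=0.3, top_x=50))
        assert set(out.edges) == {("a", "c"), ("b", "c")}

    def test_top_x_is_endpoint_union(self):
        # star: hub h with 6 leaves; each leaf's own top-1 list keeps its edge
        nodes = ("h",) + tuple(f"l{i}" for i in range(6))
        edges = {("h", f"l{i}"): 0.4 + 0.01 * i for i in range(6)}
        net = SimilarityNetwork("n", nodes, edges)
        out = sparsify(net, SparsifierConfig(cutoff=0.0, top_x=3))
        assert out.n_edges == 6

    def test_top_x_prunes_when_no_endpoint_keeps(self):
        # complete graph on 6 nodes with distinct weights; top_x=2 keeps only
        # edges in the union of per-node top-2 lists
        rng = np.random.default_rng(2)
        nodes = tuple(f"p{i}" for i in range(6))
        weights = rng.permutation(15) / 15.0
        edges = {}
        k = 0
        for i in range(6):
            for j in range(i + 1, 6):
                edges[(nodes[i], nodes[j])] = float(weights[k])
                k += 1
        net = SimilarityNetwork("n", nodes, edges)
        out = sparsify(net, SparsifierConfig(0.0, 2))
        # oracle: union over nodes of each node's top-2 incident edges
        expected = set()
        for node, lst in net.incident().items():
            for w, partner in sorted(lst, key=lambda t: (-t[0], t[1]))[:2]:
                expected.add(tuple(sorted((node, partner))))
        assert set(out.edges) == expected
        assert out.n_edges < 15

    def test_orphan_reattached_at_cutoff(self):
        net = SimilarityNetwork(
            "n",
            ("a", "b", "c", "d"),
            {("a", "b"): 0.9, ("a", "c"): 0.8, ("b", "c"): 0.7, ("c", "d"): 0.25},
        )
        out = sparsify(net, SparsifierConfig(cutoff=0.3, top_x=2, max_edges=4))
        assert out.weight("c", "d") == pytest.approx(0.30)
        assert min(out.degrees().values()) >= 1

    def test_max_edges_caps_and_keeps_strongest(self):
        rng = np.random.default_rng(4)
        net = random_network(rng, 20, density=0.5)
        out = sparsify(net, SparsifierConfig(cutoff=0.0, top_x=50, max_edges=25))
        # re-attachment may push slightly past the cap, never below node coverage
        assert out.n_edges >= 20 // 2
        kept = sorted(out.edges.values(), reverse=True)
        assert len(kept) <= 25 + 20

    def test_idempotent_and_degree_preserving(self):
        rng = np.random.default_rng(9)
        cfg = SparsifierConfig(cutoff=0.3, top_x=4, max_edges=30)
        for _ in range(10):
            net = random_network(rng, 25, density=0.3)
            s1 = sparsify(net, cfg)
            s2 = sparsify(s1, cfg)
            assert s1.edges == s2.edges
            covered = {n for n, d in net.degrees().items() if d > 0}
            deg = s1.degrees()
            assert all(deg[n] >= 1 for n in covered)

    def test_max_edges_below_node_count_rejected(self):
        net = random_network(np.random.default_rng(0), 10)
        with pytest.raises(ValueError):
            sparsify(net, SparsifierConfig(cutoff=0.0, top_x=5, max_edges=5))
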
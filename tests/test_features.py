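"""Edge labelling, κ, homogeneity, clustering, degree and distance features."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tlograph as tg
from tlograph.examples import worked_example_graph
from tlograph.features import (
    EdgeLabelSummary,
    EdgelessGraphError,
    MultiTypeError,
)

from conftest import (
    brute_force_clustering,
    brute_force_kappa,
    build_graph,
    make_cell_map,
    random_point_map,
)


class TestLabelEdges:
    def test_all_same_type_triangle(self):
        g = build_graph({"a": "T", "b": "T", "c": "T"}, [("a", "b"), ("b", "c"), ("a", "c")])
        s = tg.label_edges(g)
        assert (s.n_edges, s.n_alpha, s.gamma_counts) == (3, 3, {})
        assert s.n_alpha_a == 0  # T-T edges are alpha but not alpha_A (A=B)

    def test_b_star_all_gamma_zero(self):
        g = build_graph(
            {"b": "B", "t1": "T", "t2": "T", "t3": "T"},
            [("b", "t1"), ("b", "t2"), ("b", "t3")],
        )
        s = tg.label_edges(g)
        assert s.gamma_counts == {0: 3}
        assert s.n_alpha == 0

    def test_b_pair_with_t_leaves(self):
        g = build_graph(
            {"b1": "B", "b2": "B", "t1": "T", "t2": "T"},
            [("b1", "b2"), ("b1", "t1"), ("b2", "t2")],
        )
        s = tg.label_edges(g)
        assert s.gamma_counts == {1: 2}
        assert s.n_alpha == 1 and s.n_alpha_a == 1

    def test_multi_type_rejected(self):
        g = build_graph({"a": "B", "b": "T", "c": "X"}, [("a", "b")])
        g.graph.nodes["c"]["phenotype"] = "NK"
        with pytest.raises(MultiTypeError, match="multi-type not supported"):
            tg.label_edges(g)

    def test_labels_written_to_edges(self):
        g = build_graph(
            {"b1": "B", "b2": "B", "t1": "T"}, [("b1", "b2"), ("b1", "t1")]
        )
        tg.label_edges(g)
        assert g.graph.edges["b1", "b2"]["label"] == "alpha"
        assert g.graph.edges["b1", "t1"]["label"] == 1

    @pytest.mark.parametrize("seed", range(8))
    def test_partition_identity_and_kappa_oracle(self, seed):
        rng = np.random.default_rng(seed)
        cm = random_point_map(rng, int(rng.integers(20, 200)))
        infs = tg.build_neighborhood_graphs(cm, threshold_px=15, min_nodes=1)
        for g in infs:
            s = tg.label_edges(g)
            assert s.n_alpha + sum(s.gamma_counts.values()) == s.n_edges
            for a in (0, 1, 2, 5, 9):
                assert tg.kappa(s, a) == pytest.approx(brute_force_kappa(g, a))

    def test_relabelling_swaps_only_type_dependent_features(self):
        rng = np.random.default_rng(42)
        cm = random_point_map(rng, 80)
        (g,) = tg.build_neighborhood_graphs(cm, threshold_px=40, min_nodes=1)
        s_b = tg.label_edges(g, "B")
        h_b, c_b = tg.homogeneity(s_b), tg.clustering_coefficient(g)
        pk_b, _ = tg.degree_statistics(g)
        s_t = tg.label_edges(g, "T")
        assert s_t.n_alpha == s_b.n_alpha
        assert tg.homogeneity(s_t) == h_b
        assert tg.clustering_coefficient(g) == c_b
        assert tg.degree_statistics(g)[0] == pk_b
        assert s_t.n_alpha_a != s_b.n_alpha_a or s_b.n_alpha_a * 2 == s_b.n_alpha


class TestKappa:
    def test_worked_example(self):
        s = tg.label_edges(worked_example_graph())
        assert tg.kappa(s, 2) == pytest.approx(0.4)
        assert tg.kappa(s, 5) == pytest.approx(0.05)

    def test_no_intertype_edges_gives_zero(self):
        s = EdgeLabelSummary(n_edges=5, n_alpha=5, n_alpha_a=2, gamma_counts={})
        for a in range(6):
            assert tg.kappa(s, a) == 0.0

    def test_direct_evaluation(self):
        s = EdgeLabelSummary(n_edges=3, n_alpha=1, n_alpha_a=1, gamma_counts={1: 2})
        assert tg.kappa(s, 0) == 1.0
        assert tg.kappa(s, 1) == 0.0

    @given(
        st.dictionaries(st.integers(0, 12), st.integers(1, 30), max_size=8),
        st.integers(0, 20),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_non_increasing_and_vanishing(self, gammas, n_alpha):
        n_inter = sum(gammas.values())
        s = EdgeLabelSummary(
            n_edges=n_alpha + n_inter,
            n_alpha=n_alpha,
            n_alpha_a=0,
            gamma_counts=gammas,
        )
        values = [tg.kappa(s, a) for a in range(15)]
        assert all(x >= y for x, y in zip(values, values[1:]))
        if gammas:
            assert values[max(gammas)] == 0.0
        assert all(0.0 <= v <= 1.0 for v in values)


class TestScalarFeatures:
    def test_homogeneity_examples(self):
        all_t = tg.label_edges(
            build_graph({"a": "T", "b": "T"}, [("a", "b")])
        )
        assert tg.homogeneity(all_t) == 1.0
        single_inter = tg.label_edges(build_graph({"a": "T", "b": "B"}, [("a", "b")]))
        assert tg.homogeneity(single_inter) == 0.0
        tri = tg.label_edges(
            build_graph(
                {"a": "T", "b": "T", "c": "B"},
                [("a", "b"), ("b", "c"), ("a", "c")],
            )
        )
        assert tg.homogeneity(tri) == pytest.approx(1 / 3)

    def test_homogeneity_edgeless(self):
        s = EdgeLabelSummary(n_edges=0, n_alpha=0, n_alpha_a=0, gamma_counts={})
        with pytest.raises(EdgelessGraphError):
            tg.homogeneity(s)

    def test_clustering_examples(self):
        tri = build_graph({"a": "T", "b": "T", "c": "T"}, [("a", "b"), ("b", "c"), ("a", "c")])
        assert tg.clustering_coefficient(tri) == 1.0
        path = build_graph({"a": "T", "b": "T", "c": "T"}, [("a", "b"), ("b", "c")])
        assert tg.clustering_coefficient(path) == 0.0
        square_diag = build_graph(
            {"a": "T", "b": "T", "c": "T", "d": "T"},
            [("a", "b"), ("b", "c"), ("c", "d"), ("d", "a"), ("a", "c")],
        )
        assert tg.clustering_coefficient(square_diag) == pytest.approx(5 / 6)

    @pytest.mark.parametrize("seed", range(5))
    def test_clustering_matches_oracles(self, seed):
        import networkx as nx

        rng = np.random.default_rng(seed)
        cm = random_point_map(rng, 120)
        (g,) = tg.build_neighborhood_graphs(cm, threshold_px=60, min_nodes=1)
        ours = tg.clustering_coefficient(g)
        assert ours == pytest.approx(brute_force_clustering(g))
        assert ours == pytest.approx(nx.average_clustering(g.graph, count_zeros=True))

    def test_degree_statistics(self):
        tri = build_graph({"a": "T", "b": "T", "c": "T"}, [("a", "b"), ("b", "c"), ("a", "c")])
        p_k, avg = tg.degree_statistics(tri)
        assert p_k == {2: 1.0} and avg == 2.0
        sq = build_graph(
            {"a": "T", "b": "T", "c": "T", "d": "T"},
            [("a", "b"), ("b", "c"), ("c", "d"), ("d", "a"), ("a", "c")],
        )
        p_k, avg = tg.degree_statistics(sq)
        assert p_k == {2: 0.5, 3: 0.5}
        assert avg == pytest.approx(2.5)
        assert sum(k * p for k, p in p_k.items()) == pytest.approx(avg)

    def test_mean_pairwise_distance(self):
        two = build_graph({"a": "T", "b": "T"}, [("a", "b")])
        two.graph.nodes["a"].update(x=0.0, y=0.0)
        two.graph.nodes["b"].update(x=100.0, y=0.0)
        d, sub = tg.mean_pairwise_distance(two, 0.253)
        assert d == pytest.approx(25.3) and not sub

        sq = build_graph({"a": "T", "b": "T", "c": "T", "d": "T"}, [])
        for name, (x, y) in zip("abcd", [(0, 0), (10, 0), (10, 10), (0, 10)]):
            sq.graph.nodes[name].update(x=float(x), y=float(y))
        d, _ = tg.mean_pairwise_distance(sq, 1.0)
        assert d == pytest.approx((4 * 10 + 2 * 10 * math.sqrt(2)) / 6)

    def test_mean_pairwise_distance_subsampled_close_to_exact(self):
        rng = np.random.default_rng(3)
        cm = random_point_map(rng, 400, scale=500)
        (g,) = tg.build_neighborhood_graphs(cm, math.inf, min_nodes=1)
        exact, _ = tg.mean_pairwise_distance(g, 1.0)
        approx, flagged = tg.mean_pairwise_distance(
            g, 1.0, exact_cap=100, sample_pairs=200_000, seed=0
        )
        assert flagged
        assert approx == pytest.approx(exact, rel=0.02)

    def test_mean_pairwise_distance_undefined(self):
        one = build_graph({"a": "T"}, [])
        with pytest.raises(ValueError, match="undefined"):
            tg.mean_pairwise_distance(one, 1.0)


class TestFeatureVector:
    def test_all_t_triangle(self):
        cm = make_cell_map([(0, 0), (10, 0), (5, 8)], ["T", "T", "T"])
        (inf,) = tg.build_neighborhood_graphs(cm, 20, min_nodes=3)
        fv = tg.compute_feature_vector(inf)
        assert fv.frac_a == 0.0
        assert fv.homogeneity == 1.0
        assert fv.kappa[2] == 0.0

    def test_worked_example_kappa_map(self):
        g = worked_example_graph()
        inf = tg.InfiltrateGraph(
            graph=g.graph, threshold_px=45, designated_type_a="B", infiltrate_id="ex"
        )
        fv = tg.compute_feature_vector(inf)
        assert fv.kappa == {2: pytest.approx(0.4), 5: pytest.approx(0.05)}

    def test_internal_consistency_on_synthetic_pattern(self):
        spec = tg.SyntheticPatternSpec(class_label=tg.ClassLabel.TLO_LIKE, seed=7)
        infs = tg.build_neighborhood_graphs(tg.generate_pattern(spec))
        fv = tg.compute_feature_vector(max(infs, key=lambda g: g.n_nodes))
        assert 0.0 <= fv.homogeneity <= 1.0
        assert all(0.0 <= v <= 1.0 for v in fv.kappa.values())
        assert 0.0 <= fv.clustering_c <= 1.0
        assert 0.0 <= fv.frac_a <= 1.0
        assert sum(fv.degree_distribution.values()) == pytest.approx(1.0)
        assert fv.avg_degree == pytest.approx(2 * fv.n_edges / fv.n_nodes)
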
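"""Index of association, permutation null, topology stats and MCL."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from conftest import reference_mcl
from oligoscope.network import (
    MCLParams,
    UndefinedIAError,
    build_graph,
    cluster_summary,
    fit_degree_powerlaw,
    ia_matrix,
    ia_null,
    index_of_association,
    mcl,
    network_stats,
    rescale_edge_weights,
)


class TestIndexOfAssociation:
    def test_proportional_profiles_score_100(self):
        assert index_of_association([5, 5], [1, 1]) == pytest.approx(100.0)
        assert index_of_association([2, 4, 6], [1, 2, 3]) == pytest.approx(100.0)

    def test_disjoint_support_scores_zero(self):
        assert index_of_association([10, 0], [0, 10]) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        # (3,1) vs (1,1): 100 - (|75-50| + |25-50|)/2 = 75
        assert index_of_association([3, 1], [1, 1]) == pytest.approx(75.0)

    def test_symmetry_and_scale_invariance(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x, y = rng.integers(0, 9, size=(2, 7)) + rng.random((2, 7))
            ia_xy = index_of_association(x, y)
            assert ia_xy == pytest.approx(index_of_association(y, x))
            assert 0.0 <= ia_xy <= 100.0 + 1e-9
            assert index_of_association(x, 3.7 * x) == pytest.approx(100.0)

    def test_zero_total_rejected(self):
        with pytest.raises(UndefinedIAError):
            index_of_association([0, 0], [1, 1])

    def test_matrix_agrees_with_pairwise_calls(self):
        rng = np.random.default_rng(1)
        t = rng.integers(1, 9, size=(5, 6)).astype(float)
        m = ia_matrix(t)
        for i in range(5):
            for j in range(5):
                assert m[i, j] == pytest.approx(
                    index_of_association(t[i], t[j]), abs=1e-9
                )


class TestIANull:
    def test_proportional_pair_beats_every_permutation(self):
        # 13 distinct site values: the chance that independent row shuffles
        # re-align a proportional pair (tying the maximal IA) is ~1/13!
        rng = np.random.default_rng(0)
        base = np.arange(1.0, 14.0)
        t = np.vstack([base, 3 * base, rng.permutation(base)])
        _, p, padj = ia_null(t, n_perm=200, seed=0)
        assert p[0, 1] == 0.0
        assert padj[0, 1] < 0.05

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        t = rng.integers(1, 20, size=(6, 13)).astype(float)
        a = ia_null(t, n_perm=50, seed=3)
        b = ia_null(t, n_perm=50, seed=3)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_matrices_are_symmetric(self):
        rng = np.random.default_rng(6)
        t = rng.integers(1, 20, size=(5, 8)).astype(float)
        ia, p, padj = ia_null(t, n_perm=50, seed=1)
        for m in (ia, p, padj):
            np.testing.assert_allclose(m, m.T)


class TestBuildGraph:
    def _tables(self):
        # 8 sites with distinct values so permutation ties are negligible
        base = np.array([1.0, 2, 3, 5, 8, 13, 21, 34])
        counts = pd.DataFrame(
            [base, 2 * base, 5 * base, [1, 0, 0, 0, 0, 0, 0, 0]],
            columns=[f"s{i}" for i in range(8)],
            index=["a", "b", "c", "single"],
        ).astype(float)
        return counts

    def test_proportional_triple_forms_triangle(self):
        counts = self._tables()
        ia, _, padj = ia_null(counts.to_numpy(float), n_perm=200, seed=2)
        g = build_graph(counts, ia, padj)
        assert set(g.nodes()) == {"a", "b", "c"}  # singleton row excluded
        assert g.number_of_edges() == 3
        for _, _, d in g.edges(data=True):
            assert d["ia"] == pytest.approx(100.0)

    def test_no_passing_pair_gives_edgeless_graph(self):
        counts = pd.DataFrame(
            {"s1": [10, 0], "s2": [0, 10]}, index=["a", "b"]
        )
        ia = ia_matrix(counts.to_numpy(float))
        padj = np.ones((2, 2))
        g = build_graph(counts, ia, padj)
        assert g.number_of_nodes() == 2 and g.number_of_edges() == 0

    def test_min_abundance_filters_nodes(self):
        counts = self._tables()
        ia = ia_matrix(counts.to_numpy(float))
        g = build_graph(counts, ia, np.zeros_like(ia), min_abundance=100)
        assert set(g.nodes()) == {"b", "c"}

    def test_planted_guild_forms_one_component(self):
        """Five co-varying oligotypes among 50 neutral ones end up in one
        connected component of the IA graph in nearly every simulation."""
        rng = np.random.default_rng(77)
        hits = 0
        n_sim = 10
        for _ in range(n_sim):
            shape = rng.uniform(1, 20, size=13)
            guild = rng.poisson(shape * rng.uniform(2, 6, size=(5, 1))) + 1
            neutral = rng.poisson(5.0, size=(50, 13)) + 1
            counts = pd.DataFrame(
                np.vstack([guild, neutral]).astype(float),
                columns=[f"s{i}" for i in range(13)],
                index=[f"g{i}" for i in range(5)] + [f"n{i}" for i in range(50)],
            )
            ia, _, padj = ia_null(
                counts.to_numpy(), n_perm=200, seed=int(rng.integers(2**31))
            )
            g = build_graph(counts, ia, padj)
            comps = list(nx.connected_components(g))
            guild_nodes = {f"g{i}" for i in range(5)}
            hits += any(guild_nodes <= c for c in comps)
        assert hits >= 0.9 * n_sim


class TestNetworkStats:
    def test_complete_graph(self):
        s = network_stats(nx.complete_graph(4))
        assert s.density == 1.0
        assert s.mean_neighbors == 3.0
        assert s.centralization == pytest.approx(0.0)
        assert s.clustering_coefficient == 1.0
        assert s.heterogeneity == 0.0

    def test_star_graph(self):
        s = network_stats(nx.star_graph(4))  # hub + 4 leaves
        assert s.density == pytest.approx(0.4)
        assert s.centralization == pytest.approx(1.0)
        assert s.clustering_coefficient == 0.0

    def test_two_disjoint_triangles(self):
        g = nx.Graph()
        g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        s = network_stats(g)
        assert s.n_components == 2
        assert s.component_sizes == [3, 3]
        assert s.clustering_coefficient == 1.0

    def test_degree_conservation(self):
        g = nx.gnm_random_graph(30, 60, seed=2)
        degs = [d for _, d in g.degree()]
        assert sum(degs) == 2 * g.number_of_edges()

    def test_tiny_graph_centralization_missing(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        assert network_stats(g).centralization is None

    def test_powerlaw_fit_recovers_exact_relation(self):
        # degree histogram count = 72.6 * degree^-1.1 by construction
        degrees = []
        for d in range(1, 20):
            degrees.extend([d] * max(1, round(72.6 * d**-1.1)))
        a, b = fit_degree_powerlaw(degrees)
        assert b == pytest.approx(-1.1, abs=0.1)
        assert a == pytest.approx(72.6, rel=0.25)


class TestRescale:
    @pytest.mark.parametrize(
        "ia, expected", [(85.0, 0.001), (100.0, 0.15), (92.5, 0.0755)]
    )
    def test_linear_map(self, ia, expected):
        assert rescale_edge_weights([ia])[0] == pytest.approx(expected)

    def test_below_range_rejected(self):
        with pytest.raises(ValueError):
            rescale_edge_weights([80.0])

    def test_map_is_increasing(self):
        w = rescale_edge_weights(np.linspace(85, 100, 50))
        assert (np.diff(w) > 0).all()


class TestMCL:
    def test_two_disjoint_triangles(self):
        g = nx.Graph()
        for u, v in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
            g.add_edge(u, v, weight=90.0)
        clusters = mcl(g)
        assert sorted(map(sorted, clusters)) == [[0, 1, 2], [3, 4, 5]]

    def test_single_node(self):
        g = nx.Graph()
        g.add_node("x")
        assert mcl(g) == [{"x"}]

    def test_output_is_a_partition(self):
        rng = np.random.default_rng(4)
        g = nx.gnm_random_graph(25, 60, seed=7)
        for _, _, d in g.edges(data=True):
            d["weight"] = float(rng.uniform(85, 100))
        clusters = mcl(g)
        nodes = [n for cl in clusters for n in cl]
        assert len(nodes) == len(set(nodes)) == g.number_of_nodes()

    def test_planted_blocks_match_reference_iteration(self):
        rng = np.random.default_rng(11)
        n, blocks = 20, 4
        w = np.zeros((n, n))
        labels = np.repeat(np.arange(blocks), n // blocks)
        for i in range(n):
            for j in range(i + 1, n):
                if labels[i] == labels[j]:
                    w[i, j] = w[j, i] = rng.uniform(0.1, 0.15)
                elif rng.random() < 0.15:
                    w[i, j] = w[j, i] = 0.002
        g = nx.Graph()
        g.add_nodes_from(range(n))
        for i in range(n):
            for j in range(i + 1, n):
                if w[i, j] > 0:
                    g.add_edge(i, j, weight=w[i, j])
        ours = mcl(g, rescale=False)
        oracle = reference_mcl(w, inflation=2.5)
        assert sorted(map(sorted, ours)) == sorted(map(sorted, oracle))
        assert sorted(map(sorted, ours)) == sorted(
            sorted(np.flatnonzero(labels == b).tolist()) for b in range(blocks)
        )

    def test_inflation_must_exceed_one(self):
        with pytest.raises(ValueError):
            MCLParams(inflation=1.0)


class TestClusterSummary:
    def test_counts_and_order(self):
        meta = pd.DataFrame(
            {
                "abundance": [5, 10, 2, 8, 3],
                "phylum": ["P1", "P1", "P2", "P3", "P1"],
                "class": ["C1", "C2", "C3", "C4", "C1"],
            },
            index=list("abcde"),
        )
        out = cluster_summary([{"a", "b", "c"}, {"d", "e"}], meta)
        assert list(out["n_oligotypes"]) == [3, 2]
        assert out.iloc[0]["n_phyla"] == 2
        assert out.iloc[0]["n_classes"] == 3
        assert out.iloc[0]["max_abundance"] == 10

    def test_empty(self):
        assert cluster_summary([], pd.DataFrame(columns=["abundance"])).empty
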
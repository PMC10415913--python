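import itertools

import networkx as nx
import numpy as np
import pytest

from omicsrules.netdist import (
    MAD_SCALE,
    NetdistError,
    PairMatrix,
    ThresholdParams,
    all_pairs_wesd,
    avg_wesd,
    cecm,
    dbv_threshold,
    dissimilarity,
    mask_with_ppi,
    ppi_adjacency,
    wesd_stats,
    wv_threshold,
    wv_threshold_matrix,
)
from oracles import floyd_warshall


def pair_matrix(values, genes=None):
    values = np.asarray(values, dtype=float)
    if genes is None:
        genes = [f"g{i}" for i in range(values.shape[0])]
    return PairMatrix(list(genes), values)


class TestPairMatrix:
    def test_asymmetry_rejected(self):
        with pytest.raises(NetdistError, match="symmetric"):
            pair_matrix([[0.0, 1.0], [2.0, 0.0]])

    def test_lookup(self):
        m = pair_matrix([[0.0, 0.3], [0.3, 0.0]], genes=["a", "b"])
        assert m.loc("a", "b") == 0.3


class TestCecm:
    def test_self_pair_raw_value(self, rng):
        # identical rows with biosim 1 give raw product 1 pre-normalization
        x = rng.normal(size=(3, 10))
        r = np.corrcoef(x)
        assert r[0, 0] == pytest.approx(1.0)

    def test_extremes_map_to_range_limits(self):
        # gene pair (0,1): expr r = -1, meth r = +1 -> raw -1 (minimum)
        expr = np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0], [1.0, 3.0, 2.0]])
        meth = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [2.0, 1.0, 3.0]])
        matrix = cecm(expr, meth, ["a", "b", "c"])
        assert matrix.loc("a", "b") == pytest.approx(0.0)

    def test_minmax_property(self, rng):
        expr = rng.normal(size=(5, 12))
        meth = rng.normal(size=(5, 12))
        matrix = cecm(expr, meth, [f"g{i}" for i in range(5)])
        off = matrix.offdiag()
        assert off.min() == pytest.approx(0.0)
        assert off.max() == pytest.approx(1.0)
        assert np.all((matrix.values >= 0) & (matrix.values <= 1))

    def test_zero_variance_row_warns(self, rng):
        expr = rng.normal(size=(3, 8))
        expr[0] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            cecm(expr, rng.normal(size=(3, 8)), ["a", "b", "c"])

    def test_too_few_samples(self, rng):
        with pytest.raises(NetdistError, match="3 samples"):
            cecm(rng.normal(size=(3, 2)), rng.normal(size=(3, 2)), ["a", "b", "c"])


class TestDissimilarity:
    @pytest.mark.parametrize("value,expected", [(1.0, 0.0), (0.0, 1.0)])
    def test_complement(self, value, expected):
        m = pair_matrix([[1.0, value], [value, 1.0]])
        assert dissimilarity(m).values[0, 1] == pytest.approx(expected)

    def test_random_elementwise(self, rng):
        v = rng.random((4, 4))
        v = (v + v.T) / 2
        m = pair_matrix(v)
        np.testing.assert_allclose(dissimilarity(m).values, 1.0 - v)


class TestMaskWithPpi:
    def test_no_edge_when_h_zero(self):
        d = pair_matrix([[0.0, 0.3], [0.3, 0.0]], genes=["a", "b"])
        h = pair_matrix([[0.0, 0.0], [0.0, 0.0]], genes=["a", "b"])
        graph = mask_with_ppi(d, h)
        assert graph.number_of_edges() == 0
        assert set(graph.nodes) == {"a", "b"}

    def test_edge_weight_is_product(self):
        d = pair_matrix([[0.0, 0.3], [0.3, 0.0]], genes=["a", "b"])
        h = pair_matrix([[0.0, 1.0], [1.0, 0.0]], genes=["a", "b"])
        graph = mask_with_ppi(d, h)
        assert graph["a"]["b"]["weight"] == pytest.approx(0.3)

    def test_full_h_gives_complete_graph(self, rng):
        n = 4
        v = rng.random((n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0.0)
        d = pair_matrix(v)
        h = pair_matrix(np.ones((n, n)) - np.eye(n))
        graph = mask_with_ppi(d, h)
        assert graph.number_of_edges() == n * (n - 1) // 2

    def test_gene_missing_from_h_is_isolated(self):
        d = pair_matrix([[0.0, 0.3], [0.3, 0.0]], genes=["a", "b"])
        h = pair_matrix([[0.0]], genes=["a"])
        graph = mask_with_ppi(d, h)
        assert graph.degree("b") == 0

    def test_adjacency_from_edge_list(self):
        h = ppi_adjacency([("a", "b"), ("b", "c", 0.5), ("a", "a")], ["a", "b", "c"])
        assert h.loc("a", "b") == 1.0
        assert h.loc("b", "c") == 0.5
        assert h.loc("a", "a") == 0.0  # self-loop dropped


class TestWesd:
    def test_triangle_shortcut(self):
        graph = nx.Graph()
        graph.add_edge("p", "x", weight=0.2)
        graph.add_edge("x", "q", weight=0.3)
        graph.add_edge("p", "q", weight=0.9)
        wesd = all_pairs_wesd(graph)
        assert wesd.loc("p", "q") == pytest.approx(0.5)

    def test_single_edge(self):
        graph = nx.Graph()
        graph.add_edge("a", "b", weight=0.7)
        wesd = all_pairs_wesd(graph)
        assert wesd.loc("a", "b") == pytest.approx(0.7)
        assert wesd.loc("a", "a") == 0.0

    def test_unreachable_is_inf(self):
        graph = nx.Graph()
        graph.add_edge("a", "b", weight=0.1)
        graph.add_node("c")
        wesd = all_pairs_wesd(graph)
        assert np.isinf(wesd.loc("a", "c"))

    def test_negative_weight_rejected(self):
        graph = nx.Graph()
        graph.add_edge("a", "b", weight=-0.1)
        with pytest.raises(NetdistError, match="negative"):
            all_pairs_wesd(graph)

    def test_equals_floyd_warshall_on_random_graphs(self, rng):
        for _ in range(25):
            n = int(rng.integers(3, 30))
            density = rng.uniform(0.1, 0.6)
            edges = {}
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < density:
                        edges[(i, j)] = float(rng.uniform(0.01, 1.0))
            graph = nx.Graph()
            graph.add_nodes_from(range(n))
            for (i, j), w in edges.items():
                graph.add_edge(i, j, weight=w)
            wesd = all_pairs_wesd(graph)
            expected = floyd_warshall(n, edges)
            order = np.argsort(wesd.gene_ids)
            got = wesd.values[np.ix_(order, order)]
            idx = np.array(wesd.gene_ids)[order]
            np.testing.assert_allclose(got, expected[np.ix_(idx, idx)], atol=1e-12)

    def test_metric_properties_on_components(self, rng):
        graph = nx.gnp_random_graph(12, 0.4, seed=7)
        for u, v in graph.edges:
            graph[u][v]["weight"] = float(rng.uniform(0.05, 1.0))
        wesd = all_pairs_wesd(graph)
        v = wesd.values
        assert np.allclose(np.diag(v), 0.0)
        assert np.allclose(v, v.T)
        finite = np.isfinite(v)
        n = v.shape[0]
        for i, j, k in itertools.product(range(n), repeat=3):
            if finite[i, j] and finite[i, k] and finite[k, j]:
                assert v[i, j] <= v[i, k] + v[k, j] + 1e-9

    def test_stats_exclude_diagonal(self):
        wesd = pair_matrix([[0.0, 2.0], [2.0, 0.0]])
        stats = wesd_stats(wesd)
        assert stats["min"] == stats["max"] == stats["avg"] == 2.0


class TestWvThreshold:
    def test_diagonal_is_uv_min(self):
        wesd = pair_matrix([[0.0, 1.0, 2.0], [1.0, 0.0, 3.0], [2.0, 3.0, 0.0]])
        assert wv_threshold("g0", "g0", wesd, uv_min=0.25) == 0.25

    def test_median_distance_gives_uv_min(self):
        wesd = pair_matrix([[0.0, 1.0, 2.0], [1.0, 0.0, 3.0], [2.0, 3.0, 0.0]])
        # off-diagonal distances 1, 2, 3 -> median 2 -> pair (g0,g2) at med
        matrix = wv_threshold_matrix(wesd, uv_min=0.4)
        assert matrix.loc("g0", "g2") == pytest.approx(0.4)

    def test_hand_evaluated_value(self):
        # frozen by hand: 0.1 * (1 - 0.10*(2-1)/(1.4826*0.5)) = 0.08651018...
        # off-diag distances {0.4, 0.5, 1.0, 1.5, 2.0} -> med=1, MAD=0.5;
        # the unreachable pair is excluded from both statistics
        wesd = pair_matrix(
            [
                [0.0, 0.5, 1.0, 2.0],
                [0.5, 0.0, 0.4, 1.5],
                [1.0, 0.4, 0.0, np.inf],
                [2.0, 1.5, np.inf, 0.0],
            ]
        )
        stats = wesd_stats(wesd)
        assert stats["med"] == 1.0 and stats["mad"] == 0.5
        matrix = wv_threshold_matrix(wesd, uv_min=0.1, c1=0.10, c2=MAD_SCALE)
        assert matrix.loc("g0", "g3") == pytest.approx(0.0865101848, abs=1e-9)

    def test_unreachable_pair_falls_back_to_uv_min(self):
        wesd = pair_matrix(
            [
                [0.0, 0.5, 1.0, 2.0],
                [0.5, 0.0, 1.0, np.inf],
                [1.0, 1.0, 0.0, np.inf],
                [2.0, np.inf, np.inf, 0.0],
            ]
        )
        matrix = wv_threshold_matrix(wesd, uv_min=0.1)
        assert matrix.loc("g1", "g3") == pytest.approx(0.1)

    def test_mad_zero_degenerate_warns(self):
        wesd = pair_matrix([[0.0, 1.0, 1.0], [1.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
        with pytest.warns(UserWarning, match="degenerate"):
            matrix = wv_threshold_matrix(wesd, uv_min=0.3)
        assert np.all(matrix.values == 0.3)

    def test_monotone_decreasing_in_distance(self, rng):
        d = np.sort(rng.uniform(0.1, 3.0, 6))
        values = np.zeros((4, 4))
        values[np.triu_indices(4, 1)] = d
        wesd = pair_matrix(values + values.T)
        matrix = wv_threshold_matrix(wesd, uv_min=0.2)
        thresholds = matrix.values[np.triu_indices(4, 1)]
        assert np.all(np.diff(thresholds) < 0)  # larger distance, lower cutoff

    def test_proportional_to_uv_min(self):
        wesd = pair_matrix(
            [[0.0, 0.5, 1.5], [0.5, 0.0, 1.0], [1.5, 1.0, 0.0]]
        )
        m1 = wv_threshold_matrix(wesd, uv_min=0.1)
        m2 = wv_threshold_matrix(wesd, uv_min=0.2)
        np.testing.assert_allclose(m2.values, 2.0 * m1.values)

    def test_clamped_at_zero(self):
        wesd = pair_matrix(
            [[0.0, 0.1, 100.0], [0.1, 0.0, 0.2], [100.0, 0.2, 0.0]]
        )
        matrix = wv_threshold_matrix(wesd, uv_min=0.1)
        assert np.all(matrix.values >= 0.0)


class TestSetThresholds:
    WV = pair_matrix(
        [[0.5, 0.1, 0.2], [0.1, 0.5, 0.3], [0.2, 0.3, 0.5]],
        genes=["a", "b", "c"],
    )

    def test_two_gene_set(self):
        assert dbv_threshold({"a+", "b-"}, self.WV, 0.5) == pytest.approx(0.1)

    def test_three_gene_mean_matches_ordered_sum_oracle(self):
        from oracles import dbv_ordered_pair_sum

        got = dbv_threshold({"a+", "b+", "c-"}, self.WV, 0.5)
        assert got == pytest.approx(0.2)
        assert got == pytest.approx(dbv_ordered_pair_sum([0.1, 0.2, 0.3], 3))

    def test_singleton_gives_uv_min(self):
        assert dbv_threshold({"a+"}, self.WV, 0.42) == 0.42


class TestAvgWesd:
    WESD = pair_matrix(
        [[0.0, 0.3, 0.3], [0.3, 0.0, 0.6], [0.3, 0.6, 0.0]],
        genes=["a", "b", "c"],
    )

    def test_two_gene_rule(self):
        assert avg_wesd({"a+", "b-"}, self.WESD) == pytest.approx(0.3)

    def test_three_gene_mean(self):
        assert avg_wesd({"a+", "b+", "c-"}, self.WESD) == pytest.approx(0.4)

    def test_same_gene_both_directions_warns_zero(self):
        with pytest.warns(UserWarning, match="single gene"):
            assert avg_wesd({"a+", "a-"}, self.WESD) == 0.0

    def test_unreachable_pair_contributes_max_finite(self):
        wesd = pair_matrix(
            [[0.0, 0.4, np.inf], [0.4, 0.0, np.inf], [np.inf, np.inf, 0.0]],
            genes=["a", "b", "c"],
        )
        assert avg_wesd({"a+", "c-"}, wesd) == pytest.approx(0.4)


class TestThresholdParams:
    def test_defaults(self):
        params = ThresholdParams()
        assert params.c1 == 0.10
        assert params.c2 == pytest.approx(1.4826)
        assert params.ud_min_l == 1.0

    @pytest.mark.parametrize(
        "kwargs", [{"uv_min_s": 0.0}, {"uv_min_c": 1.5}, {"ud_min_l": 0.0},
                   {"c1": -1.0}]
    )
    def test_validation(self, kwargs):
        with pytest.raises(NetdistError):
            ThresholdParams(**kwargs)
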
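import numpy as np
import pandas as pd
import pytest

from cecosucc import (CooccurrenceNetwork, CountTable, abundance_filter,
                      build_network, intersect_networks, keystone_rank,
                      network_from_table, network_metrics,
                      spearman_edge_table)
from cecosucc.network import read_graphml, write_graphml

import oracles


def _stratum(counts: np.ndarray, age: int = 49) -> CountTable:
    ids = [f"s{i}" for i in range(counts.shape[1])]
    otus = [f"o{i}" for i in range(counts.shape[0])]
    meta = pd.DataFrame({"age_days": [age] * len(ids),
                         "diet_group": ["LL"] * len(ids),
                         "doe_id": ids},
                        index=pd.Index(ids, name="sample_id"))
    return CountTable(pd.DataFrame(counts, index=otus, columns=ids), meta)


class TestAbundanceFilter:
    def test_exactly_one_percent_excluded(self):
        # o0 at exactly 1% in every sample; o1 just above
        counts = np.array([[1, 1], [2, 2], [97, 97]])
        t = _stratum(counts)
        kept = abundance_filter(t, 49, min_fraction=0.01).otu_ids
        assert "o0" not in kept and "o1" in kept

    def test_zero_floor_keeps_any_nonzero(self):
        counts = np.array([[1, 0], [0, 0], [50, 50]])
        t = _stratum(counts)
        kept = abundance_filter(t, 49, min_fraction=0.0).otu_ids
        assert kept == ["o0", "o2"]

    def test_planted_block_passes_filter(self, rarefied_study):
        _, rt, _, truth = rarefied_study
        kept = set(abundance_filter(rt, 49).otu_ids)
        for a, b, _ in truth.edges_at_age(49):
            assert a in kept and b in kept


class TestSpearmanEdges:
    def test_comonotone_pair_retained(self):
        x = np.arange(1, 11)
        t = _stratum(np.vstack([x, 2 * x, 1000 - 3 * x]))
        edges = spearman_edge_table(t)
        pair = edges[(edges.otu_a == "o0") & (edges.otu_b == "o1")]
        assert len(pair) == 1
        assert pair.iloc[0]["rho"] == pytest.approx(1.0)
        assert pair.iloc[0]["sign"] == 1

    def test_antitone_pair_retained_with_negative_sign(self):
        x = np.arange(1, 11)
        t = _stratum(np.vstack([x, 1000 - 3 * x, np.full(10, 7) + x % 2]))
        edges = spearman_edge_table(t)
        pair = edges[(edges.otu_a == "o0") & (edges.otu_b == "o1")]
        assert pair.iloc[0]["rho"] == pytest.approx(-1.0)
        assert pair.iloc[0]["sign"] == -1

    def test_hand_rank_example_excluded_by_p_at_n5(self):
        # ranks [1,2,3,4,5] vs [1,2,3,5,4]: rho = 1 - 6*2/120 = 0.9,
        # but p at n=5 is far above the 2.32e-5 cap
        x = np.array([1, 2, 3, 4, 5])
        y = np.array([1, 2, 3, 5, 4])
        t = _stratum(np.vstack([x, y, np.array([9, 1, 4, 2, 8])]))
        edges = spearman_edge_table(t)
        assert len(edges[(edges.otu_a == "o0") & (edges.otu_b == "o1")]) == 0
        assert oracles.spearman_pair(x, y) == pytest.approx(0.9)

    def test_constant_otu_skipped_with_warning(self, caplog):
        # equal column totals keep o2's relative abundance exactly constant
        x = np.arange(1, 11)
        t = _stratum(np.vstack([x, 11 - x, np.full(10, 5)]))
        edges = spearman_edge_table(t)
        assert "constant" in caplog.text
        assert not ((edges.otu_a == "o2") | (edges.otu_b == "o2")).any()
        assert len(edges) == 1 and edges.iloc[0]["sign"] == -1

    def test_needs_four_samples(self):
        t = _stratum(np.ones((3, 3), dtype=int))
        with pytest.raises(ValueError, match="4 samples"):
            spearman_edge_table(t)

    def test_matches_rank_formula_oracle(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 100, size=(6, 12)) + 1
        t = _stratum(counts)
        rel = t.relative_abundance().to_numpy()
        edges = spearman_edge_table(t, rho_threshold=0.0, p_threshold=1.0)
        for _, row in edges.iterrows():
            i = int(row.otu_a[1:])
            j = int(row.otu_b[1:])
            assert row.rho == pytest.approx(
                oracles.spearman_pair(rel[i], rel[j]), abs=1e-12)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(1, 100, size=(5, 10))
        t1 = _stratum(counts)
        t2 = _stratum(counts[:, ::-1])
        e1 = spearman_edge_table(t1, rho_threshold=0.0, p_threshold=1.0)
        e2 = spearman_edge_table(t2, rho_threshold=0.0, p_threshold=1.0)
        pd.testing.assert_frame_equal(e1, e2)


class TestBuildNetwork:
    def test_zero_edges_keeps_nodes(self):
        t = _stratum(np.array([[5, 6, 7, 8], [8, 7, 6, 5]]))
        net = build_network(pd.DataFrame(columns=["otu_a", "otu_b", "rho",
                                                  "sign", "p_value"]), t, 49)
        assert net.n_nodes == 2 and net.n_edges == 0

    def test_duplicate_edge_rejected(self):
        t = _stratum(np.array([[5, 6, 7, 8], [8, 7, 6, 5]]))
        edges = pd.DataFrame([
            {"otu_a": "o0", "otu_b": "o1", "rho": 0.9, "sign": 1,
             "p_value": 1e-9},
            {"otu_a": "o0", "otu_b": "o1", "rho": 0.8, "sign": 1,
             "p_value": 1e-9}])
        with pytest.raises(ValueError, match="duplicate"):
            build_network(edges, t, 49)

    def test_unfiltered_otu_rejected(self):
        t = _stratum(np.array([[5, 6, 7, 8], [8, 7, 6, 5]]))
        edges = pd.DataFrame([{"otu_a": "o0", "otu_b": "oX", "rho": 0.9,
                               "sign": 1, "p_value": 1e-9}])
        with pytest.raises(ValueError, match="oX"):
            build_network(edges, t, 49)

    def test_planted_edges_recovered_at_49(self, rarefied_study):
        _, rt, _, truth = rarefied_study
        net = network_from_table(rt, 49)
        found = {frozenset((u, v)) for u, v in net.graph.edges}
        planted = {frozenset((a, b)) for a, b, _ in truth.edges_at_age(49)}
        assert len(planted & found) / len(planted) >= 0.9


class TestNetworkMetrics:
    def test_mean_degree_identity_random_graphs(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(3, 12))
            pairs = [(f"n{i}", f"n{j}") for i in range(n)
                     for j in range(i + 1, n) if rng.random() < 0.4]
            if not pairs:
                continue
            net = CooccurrenceNetwork.from_components(
                49, {u for p in pairs for u in p},
                [(u, v, 0.8) for u, v in pairs])
            m = network_metrics(net)
            assert m.mean_degree == pytest.approx(2 * m.n_edges / m.n_nodes)
            assert 0 <= m.normalized_degree <= 1

    def test_triangle_with_perfect_correlations(self):
        net = CooccurrenceNetwork.from_components(
            49, ["a", "b", "c"],
            [("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0)])
        m = network_metrics(net)
        assert m.mean_degree == pytest.approx(2.0)
        assert m.normalized_degree == pytest.approx(1.0)
        assert m.diameter == pytest.approx(0.0)   # edge lengths 1 - |rho| = 0
        assert m.hop_diameter == 1

    def test_isolates_dropped_by_default(self):
        net = CooccurrenceNetwork.from_components(
            49, ["a", "b", "c", "iso"], [("a", "b", 0.9), ("b", "c", 0.8)])
        assert network_metrics(net).n_nodes == 3
        assert network_metrics(net, drop_isolates=False).n_nodes == 4

    def test_empty_graph_errors(self):
        net = CooccurrenceNetwork.from_components(49, ["a", "b"], [])
        with pytest.raises(ValueError, match="empty"):
            network_metrics(net)

    def test_betweenness_matches_brute_force(self):
        import networkx as nx
        rng = np.random.default_rng(6)
        for _ in range(30):
            n = int(rng.integers(4, 8))
            nodes = [f"n{i}" for i in range(n)]
            edges = [(nodes[i], nodes[j]) for i in range(n)
                     for j in range(i + 1, n) if rng.random() < 0.45]
            g = nx.Graph()
            g.add_nodes_from(nodes)
            g.add_edges_from(edges)
            expect = oracles.betweenness(nodes, edges)
            got = nx.betweenness_centrality(g, normalized=True)
            for v in nodes:
                assert got[v] == pytest.approx(expect[v], abs=1e-9)


class TestIntersection:
    def _net(self, edges, nodes=None, age=43):
        nodes = nodes or sorted({u for e in edges for u in e[:2]})
        return CooccurrenceNetwork.from_components(age, nodes, edges)

    def test_self_intersection_is_identity(self):
        net = self._net([("a", "b", 0.9), ("b", "c", -0.8)])
        inter, rep = intersect_networks(net, net)
        assert inter.n_nodes == net.n_nodes and inter.n_edges == net.n_edges
        assert rep["node_conservation_vs_a"] == 100.0
        assert rep["edge_conservation_vs_b"] == 100.0

    def test_disjoint_edge_sets_empty(self):
        a = self._net([("a", "b", 0.9)], nodes=["a", "b", "c"])
        b = self._net([("b", "c", 0.9)], nodes=["a", "b", "c"], age=49)
        inter, _ = intersect_networks(a, b)
        assert inter.n_edges == 0
        assert inter.n_nodes == 3

    def test_sign_flip_not_persistent(self):
        a = self._net([("a", "b", 0.9)])
        b = self._net([("a", "b", -0.9)], age=49)
        inter, _ = intersect_networks(a, b)
        assert inter.n_edges == 0

    def test_commutative_on_sets(self):
        a = self._net([("a", "b", 0.9), ("c", "d", 0.8)],
                      nodes=list("abcde"))
        b = self._net([("a", "b", 0.95), ("d", "e", 0.8)],
                      nodes=list("abde"), age=49)
        i1, _ = intersect_networks(a, b)
        i2, _ = intersect_networks(b, a)
        assert set(i1.graph.nodes) == set(i2.graph.nodes)
        assert set(map(frozenset, i1.graph.edges)) == \
            set(map(frozenset, i2.graph.edges))

    def test_never_exceeds_parents(self):
        rng = np.random.default_rng(7)
        nodes = [f"n{i}" for i in range(10)]
        for _ in range(20):
            ea = [(nodes[i], nodes[j], 0.9) for i in range(10)
                  for j in range(i + 1, 10) if rng.random() < 0.3]
            eb = [(nodes[i], nodes[j], 0.9) for i in range(10)
                  for j in range(i + 1, 10) if rng.random() < 0.3]
            inter, rep = intersect_networks(self._net(ea, nodes),
                                            self._net(eb, nodes, age=49))
            assert inter.n_edges <= min(len(ea), len(eb))
            for k, v in rep.items():
                if k.endswith(("_a", "_b")):
                    assert v <= 100.0


class TestKeystone:
    def test_star_hub_first_with_unit_betweenness(self):
        edges = [("hub", f"leaf{i}", 0.9) for i in range(5)]
        net = CooccurrenceNetwork.from_components(49, None or
                                                  ["hub"] + [f"leaf{i}"
                                                             for i in range(5)],
                                                  edges)
        rank = keystone_rank(net)
        assert rank.iloc[0]["otu_id"] == "hub"
        assert rank.iloc[0]["betweenness"] == pytest.approx(1.0)

    def test_path_centre_has_unit_betweenness(self):
        net = CooccurrenceNetwork.from_components(
            49, ["A", "B", "C"], [("A", "B", 0.9), ("B", "C", 0.9)])
        rank = keystone_rank(net).set_index("otu_id")
        assert rank.loc["B", "betweenness"] == pytest.approx(1.0)
        assert rank.loc["A", "betweenness"] == 0.0
        assert rank.loc["C", "betweenness"] == 0.0

    def test_cycle_ties_broken_by_id(self):
        nodes = ["d", "b", "a", "c"]
        edges = [("a", "b", 0.9), ("b", "c", 0.9), ("c", "d", 0.9),
                 ("d", "a", 0.9)]
        rank = keystone_rank(CooccurrenceNetwork.from_components(
            49, nodes, edges))
        assert rank["otu_id"].tolist() == ["a", "b", "c", "d"]


class TestGraphmlRoundTrip:
    def test_round_trip(self, tmp_path):
        net = CooccurrenceNetwork.from_components(
            43, ["a", "b", "c"], [("a", "b", 0.85), ("b", "c", -0.75)])
        p = tmp_path / "net.graphml"
        write_graphml(net, p)
        back = read_graphml(p)
        assert back.age == 43
        assert set(back.graph.nodes) == {"a", "b", "c"}
        assert back.graph.edges["a", "b"]["rho"] == pytest.approx(0.85)
        assert back.graph.edges["b", "c"]["sign"] == -1
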
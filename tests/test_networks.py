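"""SparCC networks, modules, metrics, indicator species, NetShift comparison."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microdrivers import (
    CoNetwork, build_network, common_subnetwork, detect_modules, edge_significance,
    indicator_species, netshift_compare, network_metrics, sparcc, to_relative,
)
from microdrivers.networks import driver_flags, read_network, write_network
from conftest import make_table


def lognormal_counts(rng, n_taxa, n_samples, depth=30000, planted_pair_rho=None):
    z = rng.normal(size=(n_taxa, n_samples))
    if planted_pair_rho is not None:
        z[1] = planted_pair_rho * z[0] + np.sqrt(1 - planted_pair_rho ** 2) * \
            rng.normal(size=n_samples)
    w = np.exp(rng.normal(0, 1, size=(n_taxa, 1)) + z)
    rel = w / w.sum(0)
    return np.array([rng.multinomial(depth, rel[:, j]) for j in range(n_samples)]).T


def graph_network(edges) -> CoNetwork:
    g = nx.Graph()
    for u, v in edges:
        g.add_edge(u, v, weight=1.0, abs_weight=1.0)
    return CoNetwork(graph=g)


class TestSparcc:
    def test_symmetric_unit_diagonal(self, small_table):
        rho = sparcc(small_table, seed=0).to_numpy()
        np.testing.assert_allclose(rho, rho.T)
        np.testing.assert_allclose(np.diag(rho), 1.0)
        assert np.abs(rho).max() <= 1.0

    def test_planted_pair_recovered(self):
        for seed in range(3):
            rng = np.random.default_rng(seed)
            counts = lognormal_counts(rng, 20, 50, planted_pair_rho=0.9)
            rho = sparcc(make_table(counts), seed=seed)
            assert rho.iloc[0, 1] > 0.6

    def test_independent_taxa_weak_correlations(self):
        # at n = 200 the estimator noise floor sits well below 0.3
        ok, n_seeds = 0, 5
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            counts = lognormal_counts(rng, 20, 200)
            rho = sparcc(make_table(counts), seed=seed).to_numpy()
            np.fill_diagonal(rho, 0)
            ok += np.abs(rho).max() < 0.3
        assert ok / n_seeds >= 0.9

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            sparcc(make_table([[1, 2], [3, 4], [5, 6]]))


class TestEdgeSignificance:
    def test_planted_pair_minimal_p(self):
        rng = np.random.default_rng(0)
        counts = lognormal_counts(rng, 15, 40, planted_pair_rho=0.95)
        t = make_table(counts)
        rho = sparcc(t, seed=0)
        p = edge_significance(t, rho, n_bootstraps=50, seed=1)
        assert p.iloc[0, 1] == pytest.approx(1 / 51)
        assert ((p.to_numpy() > 0) & (p.to_numpy() <= 1)).all()

    def test_independent_data_p_not_concentrated(self):
        rng = np.random.default_rng(4)
        counts = lognormal_counts(rng, 10, 60)
        t = make_table(counts)
        rho = sparcc(t, seed=0)
        p = edge_significance(t, rho, n_bootstraps=50, seed=2)
        iu = np.triu_indices(10, 1)
        assert 0.25 < p.to_numpy()[iu].mean() < 0.75


class TestBuildNetwork:
    def test_zero_correlations_empty(self):
        ids = list("abcd")
        rho = pd.DataFrame(np.eye(4), index=ids, columns=ids)
        with pytest.warns(UserWarning, match="empty"):
            net = build_network(rho)
        assert net.n_edges == 0

    def test_boundary_is_strict(self):
        ids = list("ab")
        rho = pd.DataFrame([[1.0, 0.3], [0.3, 1.0]], index=ids, columns=ids)
        with pytest.warns(UserWarning):
            assert build_network(rho).n_edges == 0
        rho.iloc[0, 1] = rho.iloc[1, 0] = 0.300001
        assert build_network(rho).n_edges == 1

    def test_negative_correlations_kept_by_absolute_rule(self):
        ids = list("ab")
        rho = pd.DataFrame([[1.0, -0.8], [-0.8, 1.0]], index=ids, columns=ids)
        net = build_network(rho)
        assert net.n_edges == 1
        assert net.graph["a"]["b"]["weight"] == -0.8

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(0.1, 0.9), st.floats(0.1, 0.9))
    def test_edge_count_monotone_in_thresholds(self, r1, r2):
        rng = np.random.default_rng(0)
        m = rng.uniform(-1, 1, size=(10, 10))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        ids = [f"n{i}" for i in range(10)]
        rho = pd.DataFrame(m, index=ids, columns=ids)
        lo, hi = sorted([r1, r2])
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert build_network(rho, rho_min=hi).n_edges <= \
                build_network(rho, rho_min=lo).n_edges


class TestModules:
    def test_two_triangles_q_half(self):
        net = graph_network([("a", "b"), ("b", "c"), ("a", "c"),
                             ("x", "y"), ("y", "z"), ("x", "z")])
        detect_modules(net)
        assert net.modularity == pytest.approx(0.5)
        assert len(set(net.modules.values())) == 2

    def test_complete_graph_single_module(self):
        net = graph_network([(i, j) for i in range(5) for j in range(i + 1, 5)])
        detect_modules(net)
        assert len(set(net.modules.values())) == 1

    def test_planted_three_block_recovery(self):
        rng = np.random.default_rng(0)
        blocks = [list(range(12)), list(range(12, 24)), list(range(24, 36))]
        edges = []
        for nodes in blocks:
            for a in range(len(nodes)):
                for b in range(a + 1, len(nodes)):
                    if rng.random() < 0.8:
                        edges.append((nodes[a], nodes[b]))
        for b1 in range(3):
            for b2 in range(b1 + 1, 3):
                for a in blocks[b1]:
                    for b in blocks[b2]:
                        if rng.random() < 0.05:
                            edges.append((a, b))
        net = graph_network(edges)
        detect_modules(net)
        truth = {n: k for k, nodes in enumerate(blocks) for n in nodes}
        nodes = net.nodes
        same_truth = np.array([[truth[a] == truth[b] for b in nodes] for a in nodes])
        same_found = np.array([[net.modules[a] == net.modules[b] for b in nodes]
                               for a in nodes])
        iu = np.triu_indices(len(nodes), 1)
        rand_index = (same_truth[iu] == same_found[iu]).mean()
        assert rand_index >= 0.95

    def test_relabeling_invariance(self):
        edges = [("a", "b"), ("b", "c"), ("a", "c"), ("x", "y"), ("y", "z"), ("x", "z"),
                 ("c", "x")]
        net1 = graph_network(edges)
        mapping = {"a": "n1", "b": "n2", "c": "n3", "x": "n4", "y": "n5", "z": "n6"}
        net2 = graph_network([(mapping[u], mapping[v]) for u, v in edges])
        detect_modules(net1)
        detect_modules(net2)
        for u in mapping:
            for v in mapping:
                assert (net1.modules[u] == net1.modules[v]) == \
                    (net2.modules[mapping[u]] == net2.modules[mapping[v]])


class TestMetrics:
    def test_printed_subnetwork_degrees(self):
        # a graph with 107 nodes / 436 edges has average degree 8.15;
        # 89 nodes / 298 edges gives 6.70
        for n, e, expected in [(107, 436, 8.15), (89, 298, 6.70)]:
            g = nx.gnm_random_graph(n, e, seed=1)
            m = network_metrics(CoNetwork(graph=g))
            assert round(m.average_degree, 2) == expected

    def test_complete_k4(self):
        net = graph_network([(i, j) for i in range(4) for j in range(i + 1, 4)])
        m = network_metrics(net)
        assert m.average_degree == 3.0
        assert m.density == 1.0
        assert m.average_path_length == 1.0

    def test_path_center_betweenness(self):
        g = nx.Graph([("a", "b"), ("b", "c")])
        bet = nx.betweenness_centrality(g, normalized=True)
        assert bet["b"] == 1.0  # the convention network_metrics summarizes

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            network_metrics(CoNetwork(graph=nx.Graph()))


class TestIndicatorSpecies:
    def test_state_exclusive_taxon(self):
        counts = np.zeros((5, 20), dtype=int)
        counts[0, :10] = 50          # BT-only taxon
        counts[1:] = 20
        rel = to_relative(make_table(counts, states=["BT"] * 10 + ["AT"] * 10))
        res = indicator_species(rel, n_permutations=500, seed=0)
        assert res.per_asv.loc["A1", "indval_BT"] == pytest.approx(1.0)
        assert res.per_asv.loc["A1", "p_BT"] == pytest.approx(1 / 501)
        assert "A1" in res.significant("BT")

    def test_ubiquitous_taxon_half_indval(self):
        counts = np.full((4, 12), 25)
        rel = to_relative(make_table(counts, states=["BT"] * 6 + ["AT"] * 6))
        res = indicator_species(rel, n_permutations=200, seed=0)
        np.testing.assert_allclose(res.per_asv["indval_BT"], 0.5)
        np.testing.assert_allclose(res.per_asv["indval_AT"], 0.5)

    def test_shuffled_labels_near_alpha(self):
        rng = np.random.default_rng(1)
        hits, total = 0, 0
        for seed in range(5):
            r = np.random.default_rng(seed)
            counts = r.poisson(30, size=(40, 30))
            states = list(r.permutation(["BT"] * 15 + ["AT"] * 15))
            rel = to_relative(make_table(counts, states=states))
            res = indicator_species(rel, n_permutations=200, seed=seed)
            for s in res.states:
                hits += (res.per_asv[f"p_{s}"] < 0.05).sum()
                total += len(res.per_asv)
        assert hits / total < 0.15


def neighbor_fixture(n_bt, n_at, exclusive):
    """BT/AT star graphs giving focal node X the requested neighbor counts."""
    shared = n_at - exclusive
    shared_ids = [f"S{i}" for i in range(shared)]
    bt_only = [f"B{i}" for i in range(n_bt - shared)]
    at_only = [f"E{i}" for i in range(exclusive)]
    bt = graph_network([("X", v) for v in shared_ids + bt_only])
    at = graph_network([("X", v) for v in shared_ids + at_only])
    return bt, at


TABLE2_ROWS = [
    # node, n_bt, n_at, exclusive, printed jaccard
    ("ASV37", 1, 11, 11, 0.000), ("ASV136", 4, 13, 9, 0.308),
    ("ASV86", 2, 10, 9, 0.091), ("ASV40", 4, 4, 3, 0.143),
    ("ASV81", 3, 6, 4, 0.286), ("ASV174", 1, 5, 5, 0.000),
    ("ASV36", 3, 7, 7, 0.000), ("ASV57", 3, 3, 2, 0.200),
    ("ASV25", 1, 5, 4, 0.200), ("ASV125", 1, 11, 11, 0.000),
    ("ASV231", 5, 9, 9, 0.000), ("ASV26", 1, 2, 1, 0.500),
    ("ASV72", 2, 6, 5, 0.143), ("ASV234", 4, 3, 2, 0.167),
    ("ASV9", 3, 4, 3, 0.167), ("ASV178", 1, 4, 4, 0.000),
]


class TestNetshift:
    def test_unchanged_node(self):
        bt, at = neighbor_fixture(3, 3, 0)
        reports = {r.node: r for r in netshift_compare(bt, at)}
        x = reports["X"]
        assert x.jaccard == 1.0
        assert x.exclusive_at == 0
        assert x.nesh == 0.0

    @pytest.mark.parametrize("node,n_bt,n_at,exclusive,jaccard", TABLE2_ROWS)
    def test_neighbor_count_jaccard_identity(self, node, n_bt, n_at, exclusive, jaccard):
        bt, at = neighbor_fixture(n_bt, n_at, exclusive)
        x = {r.node: r for r in netshift_compare(bt, at)}["X"]
        assert x.n_bt == n_bt and x.n_at == n_at and x.exclusive_at == exclusive
        assert x.shared + x.exclusive_at == x.n_at
        assert round(x.jaccard, 3) == jaccard

    def test_driver_rule_union(self):
        nesh = [3.0, 2.5, 0.1, 0.2, 0.3, 0.1, 0.2, 0.1, 0.3, 0.2]
        delbet = [0.0, -0.1, 0.5, 0.0, -0.2, 0.0, 0.0, 0.0, 0.0, 0.0]
        flags = driver_flags(nesh, delbet, nesh_quantile=0.85)
        assert list(np.flatnonzero(flags)) == [0, 1, 2]

    def test_jaccard_bounds(self):
        for n_bt, n_at, exc in [(1, 5, 2), (4, 4, 0), (2, 6, 6)]:
            bt, at = neighbor_fixture(n_bt, n_at, exc)
            x = {r.node: r for r in netshift_compare(bt, at)}["X"]
            assert 0.0 <= x.jaccard <= 1.0


class TestCommonSubnetwork:
    def test_identical_networks_all_both(self):
        net = graph_network([("a", "b"), ("b", "c")])
        g = common_subnetwork(net, net)
        assert all(d["provenance"] == "both" for _, _, d in g.edges(data=True))

    def test_disjoint_edge_sets_partition(self):
        bt = graph_network([("a", "b")])
        at = graph_network([("c", "d")])
        g = common_subnetwork(bt, at)
        tags = sorted(d["provenance"] for _, _, d in g.edges(data=True))
        assert tags == ["AT-only", "BT-only"]

    def test_hand_built_tag_multiset(self):
        bt = graph_network([("a", "b"), ("b", "c"), ("c", "d")])
        at = graph_network([("b", "c"), ("c", "d"), ("d", "e")])
        g = common_subnetwork(bt, at)
        tags = sorted(d["provenance"] for _, _, d in g.edges(data=True))
        assert tags == ["AT-only", "BT-only", "both", "both"]


def test_edge_list_round_trip(tmp_path):
    net = graph_network([("a", "b"), ("b", "c")])
    net.graph["a"]["b"]["weight"] = -0.5
    write_network(net, tmp_path / "e.tsv", tmp_path / "e.graphml")
    back = read_network(tmp_path / "e.tsv")
    assert set(map(frozenset, back.graph.edges)) == set(map(frozenset, net.graph.edges))
    assert back.graph["a"]["b"]["weight"] == -0.5
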
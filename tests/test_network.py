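import itertools

import networkx as nx
import numpy as np
import pytest

from assemblage.io_tables import CommunityTable
from assemblage.network import (
    CoNetwork,
    Edge,
    build_network,
    edge_type_proportions,
    topology,
)
from assemblage.niche import GuildClassification


def net_from_edges(nodes, edges, guild=None):
    return CoNetwork(
        otu_ids=tuple(nodes),
        abundance=tuple(float(len(nodes) - i) for i in range(len(nodes))),
        edges=tuple(
            Edge(otu_a=a, otu_b=b, rho=1.0, q=0.001, sign="+") for a, b in edges
        ),
        method="spearman",
        r_threshold=0.6,
        p_threshold=0.05,
        adjustment="benjamini_hochberg",
        guild=guild,
    )


def guilds_for(nodes, labels):
    n = len(nodes)
    return GuildClassification(
        otu_ids=tuple(nodes),
        b_obs=(2.0,) * n,
        low_ci=(1.0,) * n,
        upp_ci=(3.0,) * n,
        guild=tuple(labels),
        n_perm=1000,
        r=10,
    )


def floyd_warshall_mean_path(g: nx.Graph) -> float:
    """Brute-force oracle: Floyd-Warshall over connected pairs (hops)."""
    nodes = list(g.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    inf = float("inf")
    dist = [[0.0 if i == j else inf for j in range(n)] for i in range(n)]
    for a, b in g.edges:
        dist[idx[a]][idx[b]] = dist[idx[b]][idx[a]] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i][k] + dist[k][j] < dist[i][j]:
                    dist[i][j] = dist[i][k] + dist[k][j]
    vals = [
        dist[i][j]
        for i in range(n)
        for j in range(i + 1, n)
        if dist[i][j] < inf
    ]
    return sum(vals) / len(vals) if vals else float("nan")


def exhaustive_best_modularity(g: nx.Graph) -> float:
    """Brute-force oracle: maximum modularity over all node partitions."""
    nodes = list(g.nodes)

    def partitions(seq):
        if not seq:
            yield []
            return
        first, rest = seq[0], seq[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [[first] + part[i]] + part[i + 1:]
            yield [[first]] + part

    best = -1.0
    for part in partitions(nodes):
        q = nx.community.modularity(g, [set(c) for c in part])
        best = max(best, q)
    return best


class TestTopologyClosedForms:
    def test_complete_graph_k5(self):
        nodes = [f"n{i}" for i in range(5)]
        net = net_from_edges(nodes, list(itertools.combinations(nodes, 2)))
        t = topology(net)
        assert t.avg_k == pytest.approx(4.0)
        assert t.density == pytest.approx(1.0)
        assert t.gd == pytest.approx(1.0)
        assert t.component_count == 1

    def test_path_graph_p3(self):
        net = net_from_edges(["a", "b", "c"], [("a", "b"), ("b", "c")])
        t = topology(net)
        assert t.avg_k == pytest.approx(4 / 3)
        assert t.density == pytest.approx(2 / 3)
        assert t.gd == pytest.approx(4 / 3)  # (1 + 1 + 2) / 3

    def test_two_disjoint_triangles(self):
        nodes = [f"n{i}" for i in range(6)]
        edges = [("n0", "n1"), ("n1", "n2"), ("n0", "n2"),
                 ("n3", "n4"), ("n4", "n5"), ("n3", "n5")]
        net = net_from_edges(nodes, edges)
        t = topology(net)
        assert t.density == pytest.approx(0.4)
        assert t.gd == pytest.approx(1.0)
        assert t.component_count == 2
        assert t.modularity == pytest.approx(0.5)
        # exhaustive-partition oracle confirms 0.5 is the optimum
        assert exhaustive_best_modularity(net.to_networkx()) == pytest.approx(0.5)

    def test_edgeless_network(self):
        net = net_from_edges(["a", "b", "c"], [])
        t = topology(net)
        assert t.n_edges == 0
        assert np.isnan(t.gd)
        assert np.isnan(t.modularity)
        assert any("gd undefined" in d for d in t.diagnostics)

    def test_identities_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for trial in range(20):
            n = int(rng.integers(5, 20))
            g = nx.gnp_random_graph(n, rng.random() * 0.6 + 0.1, seed=int(rng.integers(1e6)))
            g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
            net = net_from_edges(list(g.nodes), list(g.edges))
            t = topology(net)
            assert t.avg_k == pytest.approx(2 * t.n_edges / t.n_nodes)
            assert t.density == pytest.approx(
                2 * t.n_edges / (t.n_nodes * (t.n_nodes - 1))
            )

    def test_gd_matches_floyd_warshall(self):
        rng = np.random.default_rng(1)
        for trial in range(25):
            n = int(rng.integers(4, 21))
            g = nx.gnp_random_graph(n, rng.random() * 0.5 + 0.05, seed=int(rng.integers(1e6)))
            if g.number_of_edges() == 0:
                continue
            g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
            net = net_from_edges(list(g.nodes), list(g.edges))
            t = topology(net)
            assert t.gd == pytest.approx(floyd_warshall_mean_path(g))

    def test_greedy_modularity_near_optimum_on_planted_cliques(self):
        # exhaustive search is feasible up to ~10 nodes; planted two-clique
        # graphs there confirm the greedy partition is near-optimal
        for k in (3, 4, 5):
            g = nx.disjoint_union(nx.complete_graph(k), nx.complete_graph(k))
            g.add_edge(0, k)  # single bridge
            g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
            t = topology(net_from_edges(list(g.nodes), list(g.edges)))
            assert t.modularity >= exhaustive_best_modularity(g) - 0.02


class TestCoNetworkValidation:
    def test_self_edge_rejected(self):
        with pytest.raises(ValueError, match="self-edge"):
            net_from_edges(["a", "b"], [("a", "a")])

    def test_duplicate_edge_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            net_from_edges(["a", "b"], [("a", "b"), ("b", "a")])


class TestBuildNetwork:
    def make_table(self, counts):
        counts = np.asarray(counts)
        samples = tuple(f"s{j}" for j in range(counts.shape[1]))
        return CommunityTable(
            counts=counts,
            otu_ids=tuple(f"o{i}" for i in range(counts.shape[0])),
            sample_ids=samples,
            groups={s: "g" for s in samples},
        )

    def test_planted_comonotone_pair_recovered(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(1, 100, size=(10, 12))
        base = np.arange(1, 13) * 7
        counts[0] = base
        counts[1] = base * 3 + 1  # same rank order
        net = build_network(self.make_table(counts), r_threshold=0.9)
        pair = [e for e in net.edges if {e.otu_a, e.otu_b} == {"o0", "o1"}]
        assert len(pair) == 1
        assert pair[0].rho == pytest.approx(1.0)
        assert pair[0].sign == "+"

    def test_impossible_threshold_gives_empty_edges(self, small_table):
        net = build_network(small_table, r_threshold=1.01)
        assert net.edges == ()

    def test_too_few_samples(self):
        counts = np.ones((6, 4), dtype=int)
        with pytest.raises(ValueError, match="5 samples"):
            build_network(self.make_table(counts))

    def test_zero_variance_excluded_with_warning(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(1, 50, size=(8, 10))
        counts[2] = 7  # constant row
        with pytest.warns(UserWarning, match="zero-variance"):
            net = build_network(self.make_table(counts), min_prevalence=0.0)
        assert "o2" not in net.otu_ids

    def test_otu_order_invariance(self, small_table):
        net1 = build_network(small_table, r_threshold=0.7)
        rng = np.random.default_rng(5)
        perm = rng.permutation(small_table.n_otus)
        t2 = CommunityTable(
            counts=small_table.counts[perm],
            otu_ids=tuple(small_table.otu_ids[i] for i in perm),
            sample_ids=small_table.sample_ids,
            groups=small_table.groups,
        )
        net2 = build_network(t2, r_threshold=0.7)
        key = lambda e: (min(e.otu_a, e.otu_b), max(e.otu_a, e.otu_b))
        e1 = {key(e): round(e.rho, 9) for e in net1.edges}
        e2 = {key(e): round(e.rho, 9) for e in net2.edges}
        assert e1 == e2


class TestEdgeTypeProportions:
    def test_all_generalists(self):
        nodes = ["a", "b", "c"]
        net = net_from_edges(nodes, [("a", "b"), ("b", "c")])
        g = guilds_for(nodes, ["generalist"] * 3)
        etp = edge_type_proportions(net, g, scope_n=10)
        assert (etp.gg, etp.gs, etp.ss) == (1.0, 0.0, 0.0)

    def test_star_specialist_centre(self):
        nodes = ["hub", "l1", "l2", "l3", "l4"]
        net = net_from_edges(nodes, [("hub", l) for l in nodes[1:]])
        g = guilds_for(nodes, ["specialist"] + ["generalist"] * 4)
        etp = edge_type_proportions(net, g, scope_n=10)
        assert etp.gs == pytest.approx(1.0)

    def test_specialist_cluster_dominates(self):
        # dense specialist clique + sparse generalist pairs: S-S largest
        spec = [f"s{i}" for i in range(6)]
        gen = [f"g{i}" for i in range(4)]
        edges = list(itertools.combinations(spec, 2)) + [("g0", "g1"), ("g0", "s0")]
        net = net_from_edges(spec + gen, edges)
        g = guilds_for(spec + gen, ["specialist"] * 6 + ["generalist"] * 4)
        etp = edge_type_proportions(net, g, scope_n=10)
        assert etp.ss > max(etp.gg, etp.gs)
        assert etp.gg + etp.gs + etp.ss == pytest.approx(1.0)

    def test_non_significant_excluded(self):
        nodes = ["a", "b", "c"]
        net = net_from_edges(nodes, [("a", "b"), ("b", "c")])
        g = guilds_for(nodes, ["generalist", "generalist", "non_significant"])
        etp = edge_type_proportions(net, g, scope_n=10)
        assert etp.n_edges_classified == 1
        assert etp.gg == 1.0

    def test_no_labelled_edges_errors(self):
        nodes = ["a", "b"]
        net = net_from_edges(nodes, [("a", "b")])
        g = guilds_for(nodes, ["non_significant", "non_significant"])
        with pytest.raises(ValueError, match="no edges"):
            edge_type_proportions(net, g, scope_n=10)
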
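"""Centrality profiles against exhaustive path oracles, z-scoring, subgroup
rank-sum comparison, and k-core peeling against definition-level recomputation."""

import itertools

import networkx as nx
import numpy as np
import pytest

from engramnet import (
    CoactivityNetwork,
    EdgeSet,
    NeuronSet,
    centralities,
    compare_subgroups,
    kcore_peeling,
    training_edge_subgraph,
    zscore_table,
)


def _net(n, pairs, weights=None):
    w = np.zeros((n, n), dtype=np.int64)
    for k, (i, j) in enumerate(pairs):
        wt = 1 if weights is None else weights[k]
        w[i, j] = w[j, i] = wt
    return CoactivityNetwork(list(range(n)), w, 10, 1, 100, 60.0)


def brute_force_paths(n, pairs):
    """All-pairs shortest paths and path counts by exhaustive BFS enumeration."""
    adj = {i: set() for i in range(n)}
    for i, j in pairs:
        adj[i].add(j)
        adj[j].add(i)
    dist = {}
    sigma = {}
    for s in range(n):
        # BFS with path counting
        d = {s: 0}
        sig = {s: 1}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in d:
                        d[v] = d[u] + 1
                        sig[v] = 0
                        nxt.append(v)
                    if d[v] == d[u] + 1:
                        sig[v] += sig[u]
            frontier = nxt
        for t in range(n):
            if t in d:
                dist[(s, t)] = d[t]
                sigma[(s, t)] = sig[t]
    return adj, dist, sigma


def oracle_centralities(n, pairs):
    adj, dist, sigma = brute_force_paths(n, pairs)
    degree = np.array([len(adj[i]) for i in range(n)], dtype=float)
    closeness = np.zeros(n)
    for i in range(n):
        reach = [j for j in range(n) if j != i and (i, j) in dist]
        if reach:
            closeness[i] = len(reach) / sum(dist[(i, j)] for j in reach)
    betweenness = np.zeros(n)
    for i in range(n):
        for u, v in itertools.combinations([x for x in range(n) if x != i], 2):
            if (u, v) not in dist or sigma[(u, v)] == 0:
                continue
            # paths through i: d(u,i) + d(i,v) == d(u,v)
            if (u, i) in dist and (i, v) in dist and dist[(u, i)] + dist[(i, v)] == dist[(u, v)]:
                betweenness[i] += sigma[(u, i)] * sigma[(i, v)] / sigma[(u, v)]
    clustering = np.zeros(n)
    for i in range(n):
        k = len(adj[i])
        if k >= 2:
            tri = sum(1 for u, v in itertools.combinations(sorted(adj[i]), 2) if v in adj[u])
            clustering[i] = 2 * tri / (k * (k - 1))
    return degree, betweenness, closeness, clustering


class TestCentralities:
    def test_star_graph(self):
        net = _net(5, [(0, i) for i in range(1, 5)])
        t = centralities(net)
        assert t.raw["degree"][0] == 4 and all(t.raw["degree"][1:] == 1)
        assert t.raw["betweenness"][0] == 6  # one shortest path per leaf pair
        assert all(t.raw["betweenness"][1:] == 0)
        assert t.raw["clustering"][0] == 0.0

    def test_triangle(self):
        net = _net(3, [(0, 1), (1, 2), (0, 2)])
        t = centralities(net)
        assert np.allclose(t.raw["clustering"], 1.0)
        assert np.allclose(t.raw["betweenness"], 0.0)
        assert np.allclose(t.raw["eigenvector"], 1 / np.sqrt(3))

    def test_matches_exhaustive_oracle_on_random_graphs(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 13))
            pairs = [(i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < 0.3]
            net = _net(n, pairs)
            t = centralities(net)
            deg, btw, clo, clu = oracle_centralities(n, pairs)
            assert np.allclose(t.raw["degree"], deg)
            assert np.allclose(t.raw["betweenness"], btw, atol=1e-9)
            assert np.allclose(t.raw["closeness"], clo, atol=1e-9)
            assert np.allclose(t.raw["clustering"], clu, atol=1e-9)

    def test_eigenvector_uses_weights_on_lcc(self, rng):
        # two components: eigenvector support only on the larger one
        net = _net(6, [(0, 1), (1, 2), (0, 2), (4, 5)], weights=[5, 5, 5, 9])
        t = centralities(net)
        ev = t.raw["eigenvector"]
        assert ev[4] == ev[5] == 0.0 and ev[3] == 0.0
        assert np.all(ev[:3] > 0) and np.isclose(np.linalg.norm(ev), 1.0)
        # agreement with networkx on the weighted connected subgraph
        g = nx.Graph()
        g.add_weighted_edges_from([(0, 1, 5), (1, 2, 5), (0, 2, 5)])
        ref = nx.eigenvector_centrality_numpy(g, weight="weight")
        refv = np.array([ref[i] for i in range(3)])
        refv = refv / np.linalg.norm(refv)
        assert np.allclose(ev[:3], refv, atol=1e-8)


class TestZScore:
    def test_constant_metric_flagged(self):
        net = _net(4, [(0, 1), (2, 3)])  # all degrees equal
        t = zscore_table(centralities(net))
        assert "degree" in t.degenerate
        assert np.all(t.z["degree"] == 0.0)

    def test_two_point_values(self):
        net = _net(2, [(0, 1)])
        t = centralities(net)
        t.raw = {"m": np.array([0.0, 10.0])}
        zscore_table(t)
        assert np.allclose(t.z["m"], [-1.0, 1.0])  # population sd = 5

    def test_zero_mean_property(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 12))
            pairs = [(i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < 0.4]
            if not pairs:
                continue
            t = zscore_table(centralities(_net(n, pairs)))
            for m, z in t.z.items():
                assert abs(z.mean()) < 1e-9
                if m not in t.degenerate:
                    assert np.isclose(z.std(), 1.0)


class TestSubgroups:
    def _table(self, values, ne_ids):
        net = _net(len(values), [(0, 1)])
        t = centralities(net)
        t.raw = {"m": np.array(values, dtype=float)}
        t.z = {}
        zscore_table(t)
        return t, NeuronSet(set(ne_ids))

    def test_separated_groups_significant(self, rng):
        vals = list(rng.normal(0, 1, 20)) + list(rng.normal(20, 1, 20))
        t, ne = self._table(vals, set(range(20)))
        comp = compare_subgroups(t, ne)
        assert comp.p_value("m") < 1e-3
        assert comp.metrics["m"]["n_a"] == comp.metrics["m"]["n_b"] == 20

    def test_copied_distribution_not_significant(self, rng):
        base = rng.normal(0, 1, 20).tolist()
        t, ne = self._table(base + base, set(range(20)))
        assert compare_subgroups(t, ne).p_value("m") > 0.9

    def test_monotone_transform_invariance(self, rng):
        vals = rng.normal(0, 1, 30)
        t1, ne = self._table(vals.tolist(), set(range(10)))
        t2, _ = self._table(np.exp(vals).tolist(), set(range(10)))
        s1 = compare_subgroups(t1, ne).metrics["m"]["statistic"]
        s2 = compare_subgroups(t2, ne).metrics["m"]["statistic"]
        assert s1 == pytest.approx(s2)

    def test_empty_subgroup_rejected(self):
        t, _ = self._table([1.0, 2.0, 3.0], set())
        with pytest.raises(ValueError, match="non-empty"):
            compare_subgroups(t, NeuronSet(set()))


def peel_by_definition(g):
    """Recompute N(k) directly from the definition: for each k, recursively
    remove nodes of degree < k until stable, independent of core numbers."""
    occ = []
    k = 0
    while True:
        h = g.copy()
        changed = True
        while changed:
            low = [n for n, d in h.degree() if d < k]
            changed = bool(low)
            h.remove_nodes_from(low)
        if h.number_of_nodes() == 0:
            break
        occ.append(h.number_of_nodes())
        k += 1
    return occ  # occ[k] = N(k), k_max = len(occ) - 1


class TestKCore:
    def test_complete_graph_k4(self):
        g = nx.complete_graph(4)
        curve = kcore_peeling(g)
        assert curve.occupancy == [4, 4, 4, 4]
        assert curve.k_max == 3 and curve.auc_norm == pytest.approx(1.0)

    def test_triangle_with_pendant(self):
        g = nx.Graph([(0, 1), (1, 2), (0, 2), (2, 3)])
        curve = kcore_peeling(g)
        assert curve.k_max == 2 and curve.occupancy == [4, 4, 3]

    def test_edgeless_graph_flagged(self):
        g = nx.empty_graph(5)
        curve = kcore_peeling(g)
        assert curve.k_max == 0 and curve.auc_norm is None and not curve.defined

    def test_matches_definition_on_random_graphs(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 26))
            g = nx.gnp_random_graph(n, float(rng.uniform(0.1, 0.5)), seed=int(rng.integers(1e6)))
            if g.number_of_edges() == 0:
                continue
            curve = kcore_peeling(g)
            occ = peel_by_definition(g)
            assert curve.occupancy == occ
            assert curve.k_max == len(occ) - 1

    def test_edge_addition_monotonicity(self, rng):
        for _ in range(15):
            n = 12
            g = nx.gnp_random_graph(n, 0.25, seed=int(rng.integers(1e6)))
            if g.number_of_edges() == 0:
                continue
            non_edges = list(nx.non_edges(g))
            if not non_edges:
                continue
            c1 = kcore_peeling(g)
            g2 = g.copy()
            g2.add_edge(*non_edges[int(rng.integers(len(non_edges)))])
            c2 = kcore_peeling(g2)
            assert c2.k_max >= c1.k_max
            for k in range(c1.k_max + 1):
                assert c2.occupancy[k] >= c1.occupancy[k]

    def test_training_edge_subgraph_filters_both_ways(self):
        net = _net(4, [(0, 1), (1, 2), (2, 3)], weights=[3, 1, 3])
        ref = EdgeSet({(0, 1), (2, 3), (0, 3)})  # (0,3) not expressed in the session
        g = training_edge_subgraph(net, ref, min_weight=2)
        assert set(map(frozenset, g.edges())) == {frozenset({0, 1}), frozenset({2, 3})}
        assert g.number_of_nodes() == 4  # isolated nodes kept for N0
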
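"""Coactivity-network construction against a brute-force window oracle,
edge sets, summaries, and reference-edge statistics."""

import numpy as np
import pytest

from engramnet import (
    EdgeSet,
    EventRaster,
    OccupancyTrack,
    build_network,
    coactivation_frequency,
    edge_presence,
    edge_set,
    gate_raster,
    location_edges,
    network_summary,
    restricted_strength,
)
from conftest import random_raster


def brute_force_coactivity(counts, window_len=10, step=1):
    """Direct enumeration of every window position (the definition)."""
    T, N = counts.shape
    C = np.zeros((N, N), dtype=np.int64)
    for t in range(0, T - window_len + 1, step):
        act = np.nonzero(counts[t : t + window_len].sum(axis=0) > 0)[0]
        for a in range(len(act)):
            for b in range(a + 1, len(act)):
                C[act[a], act[b]] += 1
                C[act[b], act[a]] += 1
    return C


class TestBuildNetwork:
    def test_interior_coincident_events_weight_equals_window(self):
        counts = np.zeros((100, 2), dtype=int)
        counts[50, :] = 1
        net = build_network(EventRaster(counts), window_len=10)
        assert net.weights[0, 1] == 10  # covered by the 10 overlapping windows

    def test_events_at_frame_zero_single_window(self):
        counts = np.zeros((100, 2), dtype=int)
        counts[0, :] = 1
        net = build_network(EventRaster(counts), window_len=10)
        assert net.weights[0, 1] == 1

    def test_silent_neuron_has_zero_weights(self, rng):
        r = random_raster(rng, T=80, N=5, density=0.1)
        counts = r.counts.copy()
        counts[:, 2] = 0
        net = build_network(EventRaster(counts))
        assert net.weights[2].sum() == 0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(25):
            r = random_raster(rng, T=int(rng.integers(10, 200)), N=int(rng.integers(2, 10)))
            net = build_network(r)
            assert np.array_equal(net.weights, brute_force_coactivity(r.counts))

    def test_step_parameter_against_oracle(self, rng):
        r = random_raster(rng, T=95, N=6, density=0.1)
        for step in (2, 5, 10):
            net = build_network(r, window_len=10, step=step)
            assert np.array_equal(net.weights, brute_force_coactivity(r.counts, 10, step))
            assert net.n_windows == len(range(0, 95 - 10 + 1, step))

    def test_count_inflation_invariance(self, rng):
        r = random_raster(rng, T=100, N=5, density=0.1)
        inflated = EventRaster(r.counts * 7, neuron_ids=r.neuron_ids)
        assert np.array_equal(build_network(r).weights, build_network(inflated).weights)

    def test_column_permutation_consistency(self, rng):
        r = random_raster(rng, T=100, N=6, density=0.1)
        perm = rng.permutation(6)
        rp = EventRaster(r.counts[:, perm], neuron_ids=[r.neuron_ids[i] for i in perm])
        w = build_network(r).weights
        wp = build_network(rp).weights
        assert np.array_equal(wp, w[np.ix_(perm, perm)])

    def test_short_session_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            build_network(EventRaster(np.zeros((5, 2), dtype=int)), window_len=10)


class TestEdgeSet:
    def test_zero_matrix_empty(self):
        net = build_network(EventRaster(np.zeros((20, 3), dtype=int)))
        assert len(edge_set(net)) == 0

    def test_min_weight_threshold(self):
        counts = np.zeros((100, 3), dtype=int)
        counts[10, 0] = counts[10, 1] = 1  # interior -> weight 10
        counts[0, 0] = counts[0, 2] = 1  # frame 0 -> weight 1
        net = build_network(EventRaster(counts, neuron_ids=["a", "b", "c"]))
        assert edge_set(net, min_weight=1).pairs == {("a", "b"), ("a", "c")}
        assert edge_set(net, min_weight=2).pairs == {("a", "b")}

    def test_monotone_in_min_weight(self, rng):
        net = build_network(random_raster(rng, T=150, N=8, density=0.1))
        sizes = [len(edge_set(net, w)) for w in range(1, 12)]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_self_pairs_rejected(self):
        with pytest.raises(ValueError, match="self-pair"):
            EdgeSet({(1, 1)})


class TestLocationEdges:
    def test_subset_of_full_session_edges(self, rng):
        for _ in range(20):
            r = random_raster(rng, T=150, N=6, density=0.15)
            occ = OccupancyTrack([(20, 60, "locationA"), (90, 130, "locationA")], n_frames=150)
            loc = location_edges(r, occ, "locationA")
            full = edge_set(build_network(r))
            assert loc.pairs <= full.pairs

    def test_all_events_in_gate_equals_full(self):
        counts = np.zeros((100, 3), dtype=int)
        counts[30, :] = 1
        r = EventRaster(counts)
        occ = OccupancyTrack([(25, 45, "A")], n_frames=100)
        assert location_edges(r, occ, "A").pairs == edge_set(build_network(r)).pairs

    def test_missing_label_rejected(self):
        occ = OccupancyTrack([(0, 10, "other")], n_frames=50)
        with pytest.raises(ValueError, match="not present"):
            location_edges(EventRaster(np.zeros((50, 2), dtype=int)), occ, "locationA")


def _net_from_edges(node_ids, pairs, n_windows=50, duration=10.0):
    idx = {n: k for k, n in enumerate(node_ids)}
    w = np.zeros((len(node_ids), len(node_ids)), dtype=np.int64)
    for (i, j), wt in pairs.items():
        w[idx[i], idx[j]] = w[idx[j], idx[i]] = wt
    from engramnet import CoactivityNetwork

    return CoactivityNetwork(node_ids, w, 10, 1, n_windows, duration)


class TestNetworkSummary:
    def test_complete_graph(self):
        net = _net_from_edges(list("abcd"), {(a, b): 1 for a in "abcd" for b in "abcd" if a < b})
        s = network_summary(net)
        assert s.density == 1.0 and s.avg_path_length == 1.0

    def test_path_graph(self):
        net = _net_from_edges(list("abc"), {("a", "b"): 1, ("b", "c"): 1})
        s = network_summary(net)
        assert s.density == pytest.approx(2 / 3)
        assert s.avg_path_length == pytest.approx(4 / 3)

    def test_empty_graph_flagged_undefined(self):
        net = _net_from_edges(list("abcde"), {})
        s = network_summary(net)
        assert s.density == 0.0 and s.avg_path_length is None and not s.path_length_defined


class TestRestrictedStrength:
    def test_empty_reference_all_zero(self):
        net = _net_from_edges(list("abc"), {("a", "b"): 4})
        rs = restricted_strength(net, EdgeSet(set()))
        assert all(v == 0.0 for v in rs.values())

    def test_arithmetic(self):
        net = _net_from_edges(list("abc"), {("a", "b"): 4, ("a", "c"): 6}, duration=10.0)
        rs = restricted_strength(net, EdgeSet({("a", "b"), ("a", "c")}))
        assert rs["a"] == pytest.approx(1.0)
        assert rs["b"] == pytest.approx(0.4)

    def test_handshake_identity(self, rng):
        for _ in range(20):
            net = build_network(random_raster(rng, T=120, N=6, density=0.1))
            ref = edge_set(net)
            if not ref.pairs:
                continue
            rs = restricted_strength(net, ref)
            idx = net.index()
            total_w = sum(net.weights[idx[i], idx[j]] for i, j in ref.pairs)
            assert sum(rs.values()) == pytest.approx(2 * total_w / net.session_duration)


class TestReferenceEdgeStats:
    def test_edge_presence_fractions(self):
        net = _net_from_edges(list("abcd"), {("a", "b"): 2, ("a", "c"): 1, ("b", "c"): 3})
        ref = EdgeSet({("a", "b"), ("a", "c"), ("b", "c"), ("c", "d")})
        assert edge_presence(ref, net) == pytest.approx(0.75)
        full = EdgeSet({("a", "b"), ("b", "c")})
        assert edge_presence(full, net) == 1.0
        zero = _net_from_edges(list("abcd"), {})
        assert edge_presence(ref, zero) == 0.0

    def test_empty_reference_rejected(self):
        net = _net_from_edges(list("ab"), {})
        with pytest.raises(ValueError, match="empty"):
            edge_presence(EdgeSet(set()), net)
        with pytest.raises(ValueError, match="empty"):
            coactivation_frequency(EdgeSet(set()), net)

    def test_coactivation_frequency_arithmetic(self):
        net = _net_from_edges(list("abc"), {("a", "b"): 2, ("a", "c"): 4}, duration=2.0)
        ref = EdgeSet({("a", "b"), ("a", "c")})
        assert coactivation_frequency(ref, net) == pytest.approx(1.5)

    def test_relabel_invariance(self, rng):
        net = build_network(random_raster(rng, T=120, N=5, density=0.15))
        ref = edge_set(net)
        if not ref.pairs:
            pytest.skip("no edges drawn")
        relabel = {n: f"n{n}" for n in net.node_ids}
        from engramnet import CoactivityNetwork

        net2 = CoactivityNetwork(
            [relabel[n] for n in net.node_ids], net.weights, net.window_len,
            net.step, net.n_windows, net.session_duration,
        )
        ref2 = EdgeSet({(relabel[i], relabel[j]) for i, j in ref.pairs})
        assert coactivation_frequency(ref, net) == pytest.approx(coactivation_frequency(ref2, net2))
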
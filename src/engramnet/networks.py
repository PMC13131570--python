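"""Weighted coactivity networks from sliding-window event coincidence.

Two neurons are coactive in a window when each emits at least one event within
the same 1-s stretch (10 frames at 0.1 s/frame by default). The window slides
in steps of one frame across the whole session; every window position in which
a pair is jointly active increments that pair's count by one, so a single
coincident event pair contributes up to ``window_len`` counts through the
overlapping windows. The count matrix C is read as a weighted undirected
adjacency matrix with zero diagonal.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .ensembles import gate_raster
from .rasters import EventRaster, OccupancyTrack

__all__ = [
    "CoactivityNetwork",
    "EdgeSet",
    "NetworkSummary",
    "build_network",
    "edge_set",
    "location_edges",
    "network_summary",
    "restricted_strength",
    "edge_presence",
    "coactivation_frequency",
]


def _canon(i, j) -> tuple:
    """Canonical unordered pair order (low id, high id), by (typename, value)."""
    ki = (type(i).__name__, i) if not isinstance(i, str) else ("str", i)
    kj = (type(j).__name__, j) if not isinstance(j, str) else ("str", j)
    return (i, j) if ki <= kj else (j, i)


@dataclass
class CoactivityNetwork:
    """Weighted undirected graph over neurons from windowed coincidence counts."""

    node_ids: list
    weights: np.ndarray  # symmetric, non-negative integers, zero diagonal
    window_len: int
    step: int
    n_windows: int
    session_duration: float  # seconds
    session_id: str = ""

    def __post_init__(self) -> None:
        self.node_ids = list(self.node_ids)
        self.weights = np.asarray(self.weights)
        n = len(self.node_ids)
        if self.weights.shape != (n, n):
            raise ValueError("weight matrix shape must match node_ids")
        if not np.array_equal(self.weights, self.weights.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("diagonal must be zero (no self-coactivity)")
        if np.any(self.weights < 0) or np.any(self.weights > self.n_windows):
            raise ValueError("weights must lie in [0, n_windows]")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def index(self) -> dict:
        return {nid: k for k, nid in enumerate(self.node_ids)}

    def binary(self, min_weight: int = 1) -> np.ndarray:
        return (self.weights >= min_weight).astype(np.int8)

    def to_graph(self, min_weight: int = 1, weighted: bool = False) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        ii, jj = np.nonzero(np.triu(self.weights >= min_weight, k=1))
        for a, b in zip(ii.tolist(), jj.tolist()):
            if weighted:
                g.add_edge(self.node_ids[a], self.node_ids[b], weight=float(self.weights[a, b]))
            else:
                g.add_edge(self.node_ids[a], self.node_ids[b])
        return g

    def write_edge_list(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["node_i", "node_j", "weight"])
            ii, jj = np.nonzero(np.triu(self.weights, k=1))
            for a, b in zip(ii.tolist(), jj.tolist()):
                i, j = _canon(self.node_ids[a], self.node_ids[b])
                w.writerow([i, j, int(self.weights[a, b])])


@dataclass
class EdgeSet:
    """A labelled set of unordered neuron pairs in canonical (low, high) order."""

    pairs: set
    label: str = ""

    def __post_init__(self) -> None:
        canon = set()
        for i, j in self.pairs:
            if i == j:
                raise ValueError(f"self-pair ({i!r},{j!r}) is not a valid edge")
            canon.add(_canon(i, j))
        self.pairs = canon

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair) -> bool:
        return _canon(*pair) in self.pairs

    def nodes(self) -> set:
        return {n for p in self.pairs for n in p}

    def write_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["node_i", "node_j"])
            for i, j in sorted(self.pairs, key=lambda p: (str(p[0]), str(p[1]))):
                w.writerow([i, j])


@dataclass
class NetworkSummary:
    density: float
    avg_path_length: float | None  # None when the largest component has < 2 nodes
    n_nodes: int
    n_edges: int
    lcc_size: int

    @property
    def path_length_defined(self) -> bool:
        return self.avg_path_length is not None


def build_network(
    raster: EventRaster, window_len: int = 10, step: int = 1
) -> CoactivityNetwork:
    """Sliding-window coactivity count matrix for one session.

    For each window start ``t`` in {0, step, 2*step, ...} with
    ``t + window_len <= T``, every unordered pair of neurons that are each
    active (>= 1 event) somewhere in frames ``[t, t + window_len)`` has its
    count incremented by one. Only full windows are counted, so every weight
    is bounded by ``n_windows``.
    """
    T, N = raster.counts.shape
    if window_len < 1 or step < 1:
        raise ValueError("window_len and step must be >= 1")
    if T < window_len:
        raise ValueError(f"session has {T} frames, shorter than the {window_len}-frame window")
    active = (raster.counts > 0).astype(np.float64)
    # prefix sums over frames: windowed activity = any event in [t, t+L)
    cs = np.zeros((T + 1, N), dtype=np.float64)
    np.cumsum(active, axis=0, out=cs[1:])
    starts = np.arange(0, T - window_len + 1, step)
    win_active = (cs[starts + window_len] - cs[starts]) > 0  # (n_windows, N) boolean
    A = win_active.astype(np.float64)
    C = A.T @ A
    np.fill_diagonal(C, 0.0)
    weights = np.rint(C).astype(np.int64)
    return CoactivityNetwork(
        node_ids=list(raster.neuron_ids),
        weights=weights,
        window_len=window_len,
        step=step,
        n_windows=len(starts),
        session_duration=raster.duration,
        session_id=raster.session_id,
    )


def edge_set(network: CoactivityNetwork, min_weight: int = 1, label: str = "") -> EdgeSet:
    """All unordered pairs whose coactivity count reaches *min_weight*."""
    if min_weight < 1:
        raise ValueError("min_weight must be >= 1")
    ii, jj = np.nonzero(np.triu(network.weights >= min_weight, k=1))
    pairs = {_canon(network.node_ids[a], network.node_ids[b]) for a, b in zip(ii.tolist(), jj.tolist())}
    return EdgeSet(pairs, label=label or network.session_id)


def location_edges(
    raster: EventRaster,
    occupancy: OccupancyTrack,
    label: str,
    lead_frames: int = 10,
    window_len: int = 10,
    step: int = 1,
    min_weight: int = 1,
) -> EdgeSet:
    """Edges expressed within the 1-s lead or during occupancy of a location.

    Equivalent to gating the raster to the labelled epochs (plus lead) and
    taking the edge set of the gated network.
    """
    gated = gate_raster(raster, occupancy, label, lead_frames=lead_frames)
    net = build_network(gated, window_len=window_len, step=step)
    return edge_set(net, min_weight=min_weight, label=f"{label} edges ({raster.session_id})")


def network_summary(network: CoactivityNetwork, min_weight: int = 1) -> NetworkSummary:
    """Density over all node pairs and mean shortest-path length on the LCC.

    Density = 2|E| / (|V| (|V|-1)) with binary edges; isolated nodes count
    toward |V|. The average path length is the mean unweighted shortest-path
    distance over unordered pairs within the largest connected component, and
    is undefined (None) when that component has fewer than 2 nodes.
    """
    g = network.to_graph(min_weight=min_weight)
    n = g.number_of_nodes()
    if n < 1:
        raise ValueError("network has no nodes")
    m = g.number_of_edges()
    density = 0.0 if n < 2 else 2.0 * m / (n * (n - 1))
    components = list(nx.connected_components(g))
    lcc = max(components, key=len) if components else set()
    if len(lcc) < 2:
        return NetworkSummary(density, None, n, m, len(lcc))
    sub = g.subgraph(lcc)
    L = nx.average_shortest_path_length(sub)
    return NetworkSummary(density, float(L), n, m, len(lcc))


def restricted_strength(network: CoactivityNetwork, reference: EdgeSet) -> dict:
    """Per-node summed weight over reference edges, normalised by duration.

    s_i(S) = sum of W_ij over reference edges (i,j), divided by the session
    duration in seconds (units: coactive windows per second). Nodes incident
    to no reference edge get 0; reference pairs absent from the network
    contribute 0.
    """
    idx = network.index()
    out = {nid: 0.0 for nid in network.node_ids}
    for i, j in reference.pairs:
        if i in idx and j in idx:
            w = float(network.weights[idx[i], idx[j]])
            out[i] += w
            out[j] += w
    dur = network.session_duration
    return {nid: v / dur for nid, v in out.items()}


def edge_presence(reference: EdgeSet, network: CoactivityNetwork, min_weight: int = 1) -> float:
    """Fraction of reference pairs expressed (weight >= min_weight) in *network*."""
    if len(reference) == 0:
        raise ValueError("reference edge set is empty")
    idx = network.index()
    hit = 0
    for i, j in reference.pairs:
        if i in idx and j in idx and network.weights[idx[i], idx[j]] >= min_weight:
            hit += 1
    return hit / len(reference)


def coactivation_frequency(reference: EdgeSet, network: CoactivityNetwork) -> float:
    """Mean coactivity count per second over the reference pairs."""
    if len(reference) == 0:
        raise ValueError("reference edge set is empty")
    idx = network.index()
    total = 0.0
    for i, j in reference.pairs:
        if i in idx and j in idx:
            total += float(network.weights[idx[i], idx[j]])
    return total / len(reference) / network.session_duration
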
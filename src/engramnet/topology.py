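"""Node-level topology profiling and k-core robustness.

Centralities locate each neuron within the session's coactivity network:
degree (distinct coactive partners), betweenness (shortest-path brokerage,
unnormalised), closeness (within-component), eigenvector centrality (on the
weighted matrix), and clustering (triangle density). Metrics are z-scored
within a session so that positions are comparable across sessions and animals,
and the NE-specific vs non-NE subgroups are compared by two-sided rank-sum.

k-core decomposition peels nodes of degree < k recursively for k = 0, 1, ...;
the occupancy curve N(k), its maximal depth k_max, and the normalised area
under the curve summarise how much of the network persists at depth.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .ensembles import NeuronSet
from .networks import CoactivityNetwork, EdgeSet

__all__ = [
    "CentralityTable",
    "PeelingCurve",
    "SubgroupComparison",
    "METRIC_NAMES",
    "centralities",
    "zscore_table",
    "compare_subgroups",
    "kcore_peeling",
    "training_edge_subgraph",
]

METRIC_NAMES = ("degree", "betweenness", "closeness", "eigenvector", "clustering")


@dataclass
class CentralityTable:
    """Raw and z-scored node-level metrics for one session's network."""

    node_ids: list
    raw: dict  # metric name -> np.ndarray over node_ids
    z: dict = field(default_factory=dict)  # metric name -> z-scored values
    degenerate: set = field(default_factory=set)  # metrics with zero session sd
    subgroup: dict = field(default_factory=dict)  # node id -> label
    session_id: str = ""

    def values(self, metric: str, zscored: bool = False) -> np.ndarray:
        src = self.z if zscored else self.raw
        if metric not in src:
            raise KeyError(f"metric {metric!r} not available (z-scored={zscored})")
        return src[metric]

    def write_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            cols = ["neuron_id", "subgroup"]
            cols += list(self.raw) + [f"z_{m}" for m in self.z]
            w.writerow(cols)
            for k, nid in enumerate(self.node_ids):
                row = [nid, self.subgroup.get(nid, "")]
                row += [self.raw[m][k] for m in self.raw]
                row += [self.z[m][k] for m in self.z]
                w.writerow(row)


@dataclass
class PeelingCurve:
    """k-core occupancy N(k) for k = 0..k_max with its normalised AUC."""

    occupancy: list  # N(k) for k = 0 ... k_max
    n0: int
    k_max: int
    auc_norm: float | None  # None (flagged) for edgeless graphs (k_max = 0)

    def __post_init__(self) -> None:
        occ = list(self.occupancy)
        if any(b > a for a, b in zip(occ, occ[1:])):
            raise ValueError("N(k) must be non-increasing")
        if occ[0] != self.n0 or occ[-1] < 1:
            raise ValueError("curve must start at N0 and end with a non-empty core")

    @property
    def defined(self) -> bool:
        return self.auc_norm is not None

    def write_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["k", "n_nodes"])
            for k, n in enumerate(self.occupancy):
                w.writerow([k, n])

    def summary(self) -> dict:
        return {"k_max": self.k_max, "n0": self.n0, "auc_norm": self.auc_norm}


@dataclass
class SubgroupComparison:
    """Two-sided rank-sum comparison of z-scored metrics between node subgroups."""

    metrics: dict  # metric -> {"statistic","p_value","median_a","median_b","n_a","n_b"}
    group_a: str = "NE-specific"
    group_b: str = "non-NE"

    def p_value(self, metric: str) -> float:
        return self.metrics[metric]["p_value"]

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"group_a": self.group_a, "group_b": self.group_b, "metrics": self.metrics},
                      fh, indent=2, sort_keys=True)


def centralities(network: CoactivityNetwork, min_weight: int = 1) -> CentralityTable:
    """Node-level centrality profile of a coactivity network.

    Path-based metrics (degree, betweenness, closeness, clustering) use the
    binary graph; eigenvector centrality uses the weight matrix, computed on
    the largest connected component (zero elsewhere), non-negative and
    L2-normalised. Betweenness is unnormalised; closeness is the
    within-component form (|R_i| - 1) / sum d(i,j), 0 for isolated nodes.
    """
    if network.n_nodes < 2:
        raise ValueError("centrality profile needs at least 2 nodes")
    g = network.to_graph(min_weight=min_weight)
    nodes = network.node_ids
    deg = dict(g.degree())
    btw = nx.betweenness_centrality(g, normalized=False)
    clo = nx.closeness_centrality(g, wf_improved=False)
    clu = nx.clustering(g)
    eig = _eigenvector_on_lcc(network, g)
    raw = {
        "degree": np.array([float(deg[n]) for n in nodes]),
        "betweenness": np.array([float(btw[n]) for n in nodes]),
        "closeness": np.array([float(clo[n]) for n in nodes]),
        "eigenvector": np.array([eig[n] for n in nodes]),
        "clustering": np.array([float(clu[n]) for n in nodes]),
    }
    return CentralityTable(node_ids=list(nodes), raw=raw, session_id=network.session_id)


def _eigenvector_on_lcc(network: CoactivityNetwork, g: nx.Graph) -> dict:
    """Principal eigenvector of the weight matrix, restricted to the LCC."""
    out = {n: 0.0 for n in network.node_ids}
    comps = list(nx.connected_components(g))
    if not comps:
        return out
    lcc = max(comps, key=len)
    if len(lcc) < 2:
        return out
    idx = network.index()
    order = [n for n in network.node_ids if n in lcc]
    sub = network.weights[np.ix_([idx[n] for n in order], [idx[n] for n in order])].astype(np.float64)
    vals, vecs = np.linalg.eigh(sub)
    v = vecs[:, -1]
    # Perron vector of a non-negative matrix: fix sign, clip tiny negatives
    if v.sum() < 0:
        v = -v
    v = np.clip(v, 0.0, None)
    norm = np.linalg.norm(v)
    if norm > 0:
        v = v / norm
    for n, val in zip(order, v):
        out[n] = float(val)
    return out


def zscore_table(table: CentralityTable) -> CentralityTable:
    """Z-score each metric within the session (population standard deviation).

    Metrics with zero variance across the session's nodes get an all-zero
    z-column and are flagged in ``table.degenerate``.
    """
    if len(table.node_ids) < 2:
        raise ValueError("z-scoring needs at least 2 nodes")
    for metric, vals in table.raw.items():
        mu = float(np.mean(vals))
        sigma = float(np.std(vals))  # population sd, matching the session formula
        if sigma == 0.0:
            table.z[metric] = np.zeros_like(vals, dtype=np.float64)
            table.degenerate.add(metric)
        else:
            table.z[metric] = (vals - mu) / sigma
    return table


def compare_subgroups(table: CentralityTable, ne_set: NeuronSet) -> SubgroupComparison:
    """Mann-Whitney rank-sum of z-scored metrics: NE-specific vs non-NE nodes."""
    if not table.z:
        zscore_table(table)
    in_ne = np.array([nid in ne_set.ids for nid in table.node_ids])
    n_a, n_b = int(in_ne.sum()), int((~in_ne).sum())
    if n_a == 0 or n_b == 0:
        raise ValueError("both subgroups must be non-empty within the table")
    for nid, flag in zip(table.node_ids, in_ne):
        table.subgroup[nid] = "NE-specific" if flag else "non-NE"
    out: dict = {}
    for metric, vals in table.z.items():
        a, b = vals[in_ne], vals[~in_ne]
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        out[metric] = {
            "statistic": float(stat),
            "p_value": float(p),
            "median_a": float(np.median(a)),
            "median_b": float(np.median(b)),
            "n_a": n_a,
            "n_b": n_b,
        }
    return SubgroupComparison(out)


def training_edge_subgraph(network: CoactivityNetwork, reference: EdgeSet, min_weight: int = 1) -> nx.Graph:
    """Binary subgraph of the session network induced by a reference edge set.

    Keeps every network node; an edge survives if it is in the reference set
    and expressed (weight >= min_weight) in the session.
    """
    idx = network.index()
    g = nx.Graph()
    g.add_nodes_from(network.node_ids)
    for i, j in reference.pairs:
        if i in idx and j in idx and network.weights[idx[i], idx[j]] >= min_weight:
            g.add_edge(i, j)
    return g


def kcore_peeling(graph: nx.Graph | CoactivityNetwork, min_weight: int = 1) -> PeelingCurve:
    """Recursive k-core peeling curve with k_max and normalised AUC.

    For each k >= 0, nodes of degree < k are removed recursively and the
    surviving node count N(k) recorded; k_max is the largest k with a
    non-empty core. The AUC of N(k) over k = 0..k_max (trapezoidal, unit
    spacing) is normalised by its ceiling N0 * k_max, so auc_norm = 1 iff
    every node survives to the deepest core. Edgeless graphs have k_max = 0
    and an undefined (None) auc_norm rather than 0.
    """
    if isinstance(graph, CoactivityNetwork):
        graph = graph.to_graph(min_weight=min_weight)
    if graph.number_of_nodes() < 1:
        raise ValueError("peeling needs at least one node")
    g = graph.copy()
    g.remove_edges_from(nx.selfloop_edges(g))
    core = nx.core_number(g)
    k_max = max(core.values()) if core else 0
    vals = np.array(list(core.values()))
    occupancy = [int((vals >= k).sum()) for k in range(k_max + 1)]
    n0 = g.number_of_nodes()
    if k_max == 0:
        return PeelingCurve(occupancy=occupancy, n0=n0, k_max=0, auc_norm=None)
    auc = float(np.trapezoid(occupancy, dx=1.0))
    return PeelingCurve(occupancy=occupancy, n0=n0, k_max=k_max, auc_norm=auc / (n0 * k_max))
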
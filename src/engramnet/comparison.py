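"""Cross-session network comparison: similarity, turnover, and edge dynamics.

Jaccard similarity of the two sessions' binary edge sets measures how much of
the coactivity structure is preserved; turnover is its complement. Cosine
similarity compares the weighted networks. Loss, gain, and survival decompose
the fate of the reference (training) edges at recall, and the per-neuron
turnover index summarises how much of each neuron's local connectivity was
replaced.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .networks import CoactivityNetwork, EdgeSet, build_network, edge_set
from .rasters import EventRaster, RegistrationMap, align_pair

__all__ = [
    "ComparisonReport",
    "jaccard_similarity",
    "turnover",
    "cosine_similarity",
    "per_neuron_turnover",
    "edge_dynamics",
    "compare_sessions",
]


def jaccard_similarity(e1: EdgeSet, e2: EdgeSet) -> float:
    """|E1 ∩ E2| / |E1 ∪ E2| over binary edge sets."""
    union = e1.pairs | e2.pairs
    if not union:
        raise ValueError("both edge sets are empty; Jaccard is 0/0")
    return len(e1.pairs & e2.pairs) / len(union)


def turnover(e1: EdgeSet, e2: EdgeSet) -> float:
    """Fraction of edges gained or lost between sessions: 1 - Jaccard."""
    return 1.0 - jaccard_similarity(e1, e2)


def cosine_similarity(net1: CoactivityNetwork, net2: CoactivityNetwork) -> float:
    """Cosine of the two weight matrices' upper triangles.

    The networks must be aligned to the same node order. Edges absent from one
    network are zero-padded, so the value is computed over the union support
    (any fixed common support gives the same number).
    """
    if net1.node_ids != net2.node_ids:
        raise ValueError("networks must be aligned to the same ordered node set")
    iu = np.triu_indices(net1.n_nodes, k=1)
    v1 = net1.weights[iu].astype(np.float64)
    v2 = net2.weights[iu].astype(np.float64)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("cosine similarity undefined for an all-zero network")
    return float(v1 @ v2 / (n1 * n2))


def per_neuron_turnover(
    net1: CoactivityNetwork, net2: CoactivityNetwork, min_weight: int = 1
) -> tuple[dict, float]:
    """Per-neuron incident-edge turnover index Ti, in percent.

    For each neuron i with incident binary edge sets E_i(1), E_i(2),
    Ti(i) = 100 * (1 - |E_i(1) ∩ E_i(2)| / |E_i(1) ∪ E_i(2)|): the percentage
    of the neuron's connections replaced between the sessions. Neurons with no
    incident edge in either session are excluded from the mean.
    """
    if net1.node_ids != net2.node_ids:
        raise ValueError("networks must be aligned to the same ordered node set")
    b1 = net1.weights >= min_weight
    b2 = net2.weights >= min_weight
    inter = (b1 & b2).sum(axis=1)
    union = (b1 | b2).sum(axis=1)
    ti: dict = {}
    for k, nid in enumerate(net1.node_ids):
        if union[k] > 0:
            ti[nid] = 100.0 * (1.0 - inter[k] / union[k])
    if not ti:
        raise ValueError("no neuron has an incident edge in either session")
    return ti, float(np.mean(list(ti.values())))


def edge_dynamics(etrain: EdgeSet, etest: EdgeSet) -> tuple[float | None, float | None, float | None]:
    """(loss, gain, survival) of training edges at testing, in percent.

    loss     = 100 * |E_train \\ E_test| / |E_train|
    gain     = 100 * |E_test \\ E_train| / |E_test|
    survival = 100 * |E_train ∩ E_test| / |E_train|

    A component whose denominator set is empty is returned as None; the others
    are still computed.
    """
    loss = gain = survival = None
    if len(etrain) > 0:
        n = len(etrain)
        inter = len(etrain.pairs & etest.pairs)
        loss = 100.0 * (n - inter) / n
        survival = 100.0 * inter / n
    if len(etest) > 0:
        gain = 100.0 * len(etest.pairs - etrain.pairs) / len(etest)
    if loss is None and gain is None:
        raise ValueError("both edge sets are empty; edge dynamics undefined")
    return loss, gain, survival


@dataclass
class ComparisonReport:
    """Per-animal cross-session statistics for one ordered session pair."""

    session_a: str
    session_b: str
    n_shared_neurons: int
    jaccard: float
    turnover: float
    cosine: float
    mean_edge_turnover_ti: float
    per_neuron_ti: dict
    loss_rate: float | None
    gain_rate: float | None
    survival_rate: float | None

    def __post_init__(self) -> None:
        if abs(self.jaccard + self.turnover - 1.0) > 1e-12:
            raise ValueError("jaccard + turnover must equal 1")
        if self.loss_rate is not None and self.survival_rate is not None:
            if abs(self.loss_rate + self.survival_rate - 100.0) > 1e-9:
                raise ValueError("survival + loss must equal 100")
        for frac in (self.jaccard, self.turnover, self.cosine):
            if not -1e-12 <= frac <= 1.0 + 1e-12:
                raise ValueError("fractions must lie in [0, 1]")
        for pct in (self.mean_edge_turnover_ti, self.loss_rate, self.gain_rate, self.survival_rate):
            if pct is not None and not -1e-9 <= pct <= 100.0 + 1e-9:
                raise ValueError("percents must lie in [0, 100]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["per_neuron_ti"] = {str(k): v for k, v in self.per_neuron_ti.items()}
        return d

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def compare_sessions(
    raster_a: EventRaster,
    raster_b: EventRaster,
    regmap: RegistrationMap,
    window_len: int = 10,
    step: int = 1,
    min_weight: int = 1,
) -> ComparisonReport:
    """Full cross-session comparison on the shared-neuron subspace.

    Both rasters are aligned to the neurons registered in both sessions, the
    coactivity networks are built on that common node set, and all statistics
    are computed with session A as the reference (training-like) session.
    """
    a, b, shared = align_pair(raster_a, raster_b, regmap)
    net_a = build_network(a, window_len=window_len, step=step)
    net_b = build_network(b, window_len=window_len, step=step)
    e_a = edge_set(net_a, min_weight=min_weight, label=raster_a.session_id)
    e_b = edge_set(net_b, min_weight=min_weight, label=raster_b.session_id)
    jac = jaccard_similarity(e_a, e_b)
    cos = cosine_similarity(net_a, net_b)
    per_ti, mean_ti = per_neuron_turnover(net_a, net_b, min_weight=min_weight)
    loss, gain, survival = edge_dynamics(e_a, e_b)
    return ComparisonReport(
        session_a=raster_a.session_id,
        session_b=raster_b.session_id,
        n_shared_neurons=len(shared),
        jaccard=jac,
        turnover=1.0 - jac,
        cosine=cos,
        mean_edge_turnover_ti=mean_ti,
        per_neuron_ti=per_ti,
        loss_rate=loss,
        gain_rate=gain,
        survival_rate=survival,
    )
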
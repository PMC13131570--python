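"""Synthetic multi-session event rasters with full ground truth.

The generator emulates the study's five-session design (training, two
post-learning reactivation sessions at 0.5 h and 4 h, novelty exploration,
and memory testing) at 10 Hz for ~10-minute sessions, with:

* an engram with core-periphery coactivity structure (dense core-core edges,
  sparser core-periphery and periphery-periphery edges) over silent background
  neurons;
* session-to-session edge retention (a controlled fraction q of training edges
  reappears at testing) and edge gain (a fraction g of testing edges is new);
* post-learning maturation: shortly after learning only part of the ensemble
  re-engages (node-level reactivation probability), so the early network is a
  sparse induced fragment of the training network; the maturation multiplier m
  scales the re-engaged fraction, and the late session expresses the training
  structure in full at m >= 1/reactivation_base;
* NE-neuron infiltration at controlled topological depth: infiltrating
  neurons, silent during training, attach either to the highest-degree core
  of the engram (effective interference — the attachments persist into the
  recall network) or to its low-degree periphery (non-effective — expressed
  only during novelty exploration).

Event placement uses a non-overlapping slot lattice: every activation packet
(a pairwise co-activation or a background single) occupies its own slot,
spaced so that events from different packets can never fall inside the same
1-s coincidence window. Edges detected by the sliding-window network
construction are therefore exactly the scheduled ones, which is what makes
retention, gain, maturation, and infiltration depth recoverable from the
rasters. Real rasters are of course not lattice-structured; see the package
documentation for what this does and does not emulate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .rasters import (
    AnimalRecord,
    EventRaster,
    OccupancyTrack,
    RegistrationMap,
)

__all__ = [
    "GeneratorParams",
    "GroundTruth",
    "SessionBundle",
    "SESSIONS",
    "make_ground_truth",
    "session_edge_list",
    "simulate_session",
    "simulate_animal",
    "simulate_cohort",
    "animal_seed",
]

SESSIONS = ("training", "post_early", "post_late", "NE", "test")

# salts for deterministic sub-streams derived from the ground-truth seed
_SALT_TEST = 101
_SALT_POST = 103
_SALT_NE = 107
_SALT_OCC = 109


@dataclass
class GeneratorParams:
    """Study conditions for the generator (defaults are the package's own
    realistic choices for a 10-min, 10-Hz, ~150-neuron CA1 recording).

    Rates are in events per second per neuron (background) or co-activations
    per second per edge. ``q_remember`` matches the observed ~50% training-edge
    survival of unimpaired animals; the forgetting group sits ``effect_size``
    within-group standard deviations below/above on the retention and gain
    channels respectively.
    """

    n_core: int = 40
    n_periph: int = 60
    n_background: int = 40
    n_ne: int = 10
    p_cc: float = 0.20
    p_cp: float = 0.04
    p_pp: float = 0.02
    attachments: int | str = "match"  # fixed count, or "match" the engram degree distribution
    n_frames: int = 6000
    frame_period: float = 0.1
    window_len: int = 10
    offset_span: int = 5  # co-event offsets are uniform in [0, offset_span)
    lambda_bg: float = 0.001  # background event rate (s^-1)
    lambda_edge: float = 0.002  # co-activation rate per expressed edge (s^-1)
    q_remember: float = 0.5
    g_remember: float = 0.30
    diffuseness_remember: float = 0.35  # how evenly edge loss spreads over neurons
    sigma_q: float = 0.05
    sigma_g: float = 0.04
    sigma_diffuseness: float = 0.075
    # within-animal nuisance correlation between retention and gain: animals
    # differ in overall coactivity expressivity (event detection, excitability),
    # which inflates retained and newly formed edges together; interference
    # instead moves the two in opposite directions
    rho_qg: float = 0.5
    effect_size: float = 2.0  # group effect in within-group sd units, on q and g
    reactivation_base: float = 0.5  # fraction of the ensemble re-engaged, early post session
    maturation_m: float = 2.0
    ne_reactivation_remember: float = 0.5  # engram edges re-expressed during NE
    ne_reactivation_forget: float = 0.25
    infiltration: bool = True  # attach NE nodes at all (False -> pure outcome-channel cohorts)

    @property
    def q_forget(self) -> float:
        return self.q_remember - self.effect_size * self.sigma_q

    @property
    def g_forget(self) -> float:
        return self.g_remember + self.effect_size * self.sigma_g

    @property
    def diffuseness_forget(self) -> float:
        return min(1.0, self.diffuseness_remember + self.effect_size * self.sigma_diffuseness)


@dataclass
class GroundTruth:
    """Everything needed to re-derive what the analysis should recover."""

    seed: int
    node_ids: list
    roles: dict  # node id -> core | periphery | background | ne
    training_edges: list  # canonical (i, j) pairs, sorted
    ne_edges: list
    infiltration_mode: str  # core | peripheral | none
    q: float  # training-edge retention fraction into testing
    g: float  # fraction of testing edges that are new
    loss_diffuseness: float  # 1 = uniform edge loss; 0 = whole neurons drift out
    maturation_m: float
    reactivation_base: float
    ne_reactivation: float
    lambda_bg: float
    lambda_edge: float
    window_len: int = 10
    offset_span: int = 5

    def nodes_with_role(self, *roles: str) -> list:
        return [n for n in self.node_ids if self.roles[n] in roles]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["roles"] = {str(k): v for k, v in self.roles.items()}
        d["training_edges"] = [list(p) for p in self.training_edges]
        d["ne_edges"] = [list(p) for p in self.ne_edges]
        return d

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


@dataclass
class SessionBundle:
    """One synthetic animal: rasters, registration, occupancy, labels, truth."""

    animal_id: str
    scenario: str
    rasters: dict  # session id -> EventRaster
    regmap: RegistrationMap
    occupancy: dict  # session id -> OccupancyTrack
    ground_truth: GroundTruth
    record: AnimalRecord


def make_ground_truth(
    n_core: int,
    n_periph: int,
    n_background: int,
    n_ne: int,
    seed: int,
    p_cc: float = 0.30,
    p_cp: float = 0.03,
    p_pp: float = 0.01,
    infiltration_mode: str = "none",
    attachments: int | str = "match",
    q: float = 0.5,
    g: float = 0.30,
    loss_diffuseness: float = 0.35,
    maturation_m: float = 2.0,
    reactivation_base: float = 0.5,
    ne_reactivation: float = 0.5,
    lambda_bg: float = 0.001,
    lambda_edge: float = 0.0025,
    window_len: int = 10,
    offset_span: int = 5,
) -> GroundTruth:
    """Sample a core-periphery training edge list and NE attachments.

    Core-core pairs connect with probability ``p_cc``, core-periphery with
    ``p_cp``, periphery-periphery with ``p_pp`` (p_cc > p_cp > p_pp for a
    core-periphery profile). NE nodes attach to existing engram nodes: in
    ``core`` mode to the top-degree tercile, in ``peripheral`` mode to the
    bottom tercile, in ``none`` mode not at all. The attachment count per NE
    node is either a fixed integer or (``"match"``) resampled from the current
    engram degree distribution, which makes infiltrators degree-exchangeable
    with engram members.
    """
    if n_core + n_periph < 2:
        raise ValueError("need at least 2 engram (core + periphery) nodes")
    if min(n_core, n_periph, n_background, n_ne) < 0:
        raise ValueError("counts must be non-negative")
    for p in (p_cc, p_cp, p_pp):
        if not 0.0 <= p <= 1.0:
            raise ValueError("edge probabilities must lie in [0, 1]")
    if infiltration_mode not in ("core", "peripheral", "none"):
        raise ValueError("infiltration_mode must be 'core', 'peripheral' or 'none'")
    rng = np.random.default_rng(seed)
    node_ids = list(range(n_core + n_periph + n_background + n_ne))
    roles = {}
    core = node_ids[:n_core]
    periph = node_ids[n_core : n_core + n_periph]
    background = node_ids[n_core + n_periph : n_core + n_periph + n_background]
    ne = node_ids[n_core + n_periph + n_background :]
    for n in core:
        roles[n] = "core"
    for n in periph:
        roles[n] = "periphery"
    for n in background:
        roles[n] = "background"
    for n in ne:
        roles[n] = "ne"

    engram = core + periph
    edges: set = set()
    for a_idx in range(len(engram)):
        for b_idx in range(a_idx + 1, len(engram)):
            a, b = engram[a_idx], engram[b_idx]
            ra, rb = roles[a], roles[b]
            if ra == "core" and rb == "core":
                p = p_cc
            elif ra == "periphery" and rb == "periphery":
                p = p_pp
            else:
                p = p_cp
            if rng.random() < p:
                edges.add((a, b))

    degree = {n: 0 for n in engram}
    for a, b in edges:
        degree[a] += 1
        degree[b] += 1

    ne_edges: set = set()
    if infiltration_mode != "none":
        for n in ne:
            ranked = sorted(engram, key=lambda x: (degree[x], x))
            third = max(1, len(ranked) // 3)
            pool = ranked[-third:] if infiltration_mode == "core" else ranked[:third]
            if attachments == "match":
                a_count = int(degree[engram[rng.integers(len(engram))]])
            else:
                a_count = int(attachments)
            a_count = min(a_count, len(pool))
            targets = rng.choice(len(pool), size=a_count, replace=False)
            for t in targets:
                tgt = pool[int(t)]
                ne_edges.add((min(n, tgt), max(n, tgt)))
                degree[tgt] += 1

    return GroundTruth(
        seed=int(seed),
        node_ids=node_ids,
        roles=roles,
        training_edges=sorted(edges),
        ne_edges=sorted(ne_edges),
        infiltration_mode=infiltration_mode,
        q=q,
        g=g,
        loss_diffuseness=loss_diffuseness,
        maturation_m=maturation_m,
        reactivation_base=reactivation_base,
        ne_reactivation=ne_reactivation,
        lambda_bg=lambda_bg,
        lambda_edge=lambda_edge,
        window_len=window_len,
        offset_span=offset_span,
    )


def _exact_retention(
    pairs: list, q: float, rng: np.random.Generator, diffuseness: float = 1.0
) -> list:
    """Retain exactly round(q * |pairs|) edges.

    ``diffuseness`` controls how the complementary loss distributes over
    neurons while leaving the retained COUNT fixed: at 1 the lost edges are a
    uniform random subset; toward 0 the loss concentrates on a few nodes whose
    whole connectivity drifts out (edges are dropped in increasing order of a
    mixed node/edge score). Survival, loss and gain rates are therefore
    unaffected by diffuseness; only their distribution across neurons (hence
    the per-neuron turnover index) responds to it.
    """
    n_keep = int(round(q * len(pairs)))
    if n_keep >= len(pairs):
        return list(pairs)
    if n_keep <= 0:
        return []
    nodes = sorted({n for p in pairs for n in p})
    node_score = {n: x for n, x in zip(nodes, rng.random(len(nodes)))}
    edge_u = rng.random(len(pairs))
    score = np.array(
        [
            (1.0 - diffuseness) * min(node_score[i], node_score[j]) + diffuseness * u
            for (i, j), u in zip(pairs, edge_u)
        ]
    )
    keep_idx = np.argsort(score, kind="stable")[len(pairs) - n_keep :]
    return [pairs[i] for i in sorted(keep_idx.tolist())]


def session_edge_list(gt: GroundTruth, session_id: str) -> list:
    """The ground-truth active edge list for one session.

    Deterministic given the ground truth: the retention, gain, maturation and
    NE-reactivation draws use sub-streams seeded from ``gt.seed`` only, so any
    session can be re-derived independently of simulation order.

    * training: all training edges.
    * test: exactly round(q*E) retained training edges, new (gained) pairs to
      bring the new-edge fraction to g, and — in core infiltration mode — NE
      attachments thinned by the same q (infiltration that reached the core
      persists into recall; peripheral attachments do not). Each persisting
      attachment displaces one retained training edge of its target: the
      infiltrator takes over part of the hub's coactivity budget, which is
      what makes core contamination destructive.
    * post_early / post_late: reactivation is node-level — a neuron re-engages
      when its latent uniform falls below rho (early) or min(1, m*rho) (late),
      and a training edge is expressed when both endpoints re-engage. The late
      node set contains the early one, so the late edge list contains the
      early one and the maturation direction (density, presence, core depth)
      is generative rather than incidental.
    * NE: the NE attachments plus a ne_reactivation fraction of training edges.
    """
    if session_id == "training":
        return list(gt.training_edges)
    if session_id == "test":
        rng = np.random.default_rng(np.random.SeedSequence([gt.seed, _SALT_TEST]))
        retained = _exact_retention(gt.training_edges, gt.q, rng, diffuseness=gt.loss_diffuseness)
        retained_ne = (
            _exact_retention(gt.ne_edges, gt.q, rng) if gt.infiltration_mode == "core" else []
        )
        # persisting infiltration displaces retained engram edges at the target
        for _, t in [sorted(p, key=lambda x: (gt.roles[x] != "ne", x)) for p in retained_ne]:
            incident = [e for e in retained if t in e]
            if incident:
                retained.remove(incident[int(rng.integers(len(incident)))])
        active_nodes = sorted({n for p in gt.training_edges for n in p})
        if gt.infiltration_mode == "core":
            active_nodes = sorted(set(active_nodes) | {n for p in gt.ne_edges for n in p})
        existing = set(gt.training_edges) | set(gt.ne_edges)
        candidates = [
            (a, b)
            for i, a in enumerate(active_nodes)
            for b in active_nodes[i + 1 :]
            if (a, b) not in existing
        ]
        n_base = len(retained) + len(retained_ne)
        n_gain = int(round(gt.g / (1.0 - gt.g) * n_base)) if gt.g < 1.0 else len(candidates)
        n_gain = min(n_gain, len(candidates))
        gained = []
        if n_gain > 0:
            idx = rng.choice(len(candidates), size=n_gain, replace=False)
            gained = [candidates[i] for i in sorted(idx.tolist())]
        return sorted(set(retained) | set(retained_ne) | set(gained))
    if session_id in ("post_early", "post_late"):
        rng = np.random.default_rng(np.random.SeedSequence([gt.seed, _SALT_POST]))
        u = {n: x for n, x in zip(gt.node_ids, rng.random(len(gt.node_ids)))}
        rho = gt.reactivation_base
        if session_id == "post_late":
            rho = min(1.0, gt.maturation_m * rho)
        return [e for e in gt.training_edges if u[e[0]] < rho and u[e[1]] < rho]
    if session_id == "NE":
        rng = np.random.default_rng(np.random.SeedSequence([gt.seed, _SALT_NE]))
        u = rng.random(len(gt.training_edges))
        react = [e for e, ue in zip(gt.training_edges, u) if ue < gt.ne_reactivation]
        return sorted(set(gt.ne_edges) | set(react))
    raise ValueError(f"unknown session {session_id!r}; expected one of {SESSIONS}")


def _slot_lattice(T: int, window_len: int, offset_span: int) -> tuple[int, int]:
    """(spacing, capacity) of the non-overlapping placement lattice.

    Events inside a slot sit at offsets < offset_span from the slot start, so
    two events in the same slot are at most offset_span - 1 frames apart
    (always inside one window) and events in different slots are at least
    spacing - offset_span + 1 >= window_len apart (never inside one window).
    """
    spacing = window_len + offset_span - 1
    capacity = (T - offset_span) // spacing + 1 if T >= offset_span else 0
    return spacing, capacity


def simulate_session(
    gt: GroundTruth,
    session_id: str,
    T: int | None = None,
    frame_period: float = 0.1,
    seed: int = 0,
    T_default: int = 6000,
) -> EventRaster:
    """Render one session's event raster from the ground truth.

    Every expressed edge emits ``1 + Poisson(lambda_edge * duration - 1)``
    co-activation packets (at least one — an edge listed as active in a
    session is, by definition, observed there). Background singles arrive at
    ``lambda_bg`` per neuron; NE-specific neurons are kept silent during
    training and get solo packets during novelty exploration so they are
    detectably NE-active. All packets are placed on the non-overlapping slot
    lattice (see module docstring).
    """
    T = int(T) if T is not None else T_default
    if T < gt.window_len:
        raise ValueError("session must be at least one coincidence window long")
    rng = np.random.default_rng(np.random.SeedSequence([seed]))
    duration = T * frame_period
    edges = session_edge_list(gt, session_id)

    mean_co = gt.lambda_edge * duration
    primary: list = []  # one packet per expressed edge, protected under truncation
    extras: list = []
    if gt.lambda_edge > 0:
        extra_counts = rng.poisson(max(0.0, mean_co - 1.0), size=len(edges))
        for e, k in zip(edges, extra_counts):
            primary.append(e)
            extras.extend([e] * int(k))

    ne_nodes = gt.nodes_with_role("ne")
    singles: list = []
    for n in gt.node_ids:
        role = gt.roles[n]
        if role == "ne" and session_id == "training":
            continue  # NE-specific neurons are silent during training
        k = rng.poisson(gt.lambda_bg * duration)
        if role == "ne" and session_id == "NE":
            k += 1 + rng.poisson(1.0)  # solo activity marking the neuron as NE-active
        singles.extend([n] * int(k))

    spacing, capacity = _slot_lattice(T, gt.window_len, gt.offset_span)
    rng.shuffle(primary)
    tail = extras + singles
    rng.shuffle(tail)
    packets = (primary + tail)[:capacity]
    counts = np.zeros((T, len(gt.node_ids)), dtype=np.int64)
    if packets:
        slots = rng.choice(capacity, size=len(packets), replace=False)
        col = {n: j for j, n in enumerate(gt.node_ids)}
        for packet, slot in zip(packets, slots.tolist()):
            start = slot * spacing
            if isinstance(packet, tuple):
                i, j = packet
                counts[start + rng.integers(gt.offset_span), col[i]] += 1
                counts[start + rng.integers(gt.offset_span), col[j]] += 1
            else:
                counts[start + rng.integers(gt.offset_span), col[packet]] += 1
    return EventRaster(
        counts, frame_period=frame_period, session_id=session_id, neuron_ids=list(gt.node_ids)
    )


def _occupancy_track(T: int, rng: np.random.Generator) -> OccupancyTrack:
    """Alternating location-A / elsewhere epochs with jittered dwell times."""
    epochs = []
    t = 0
    at_a = False
    while t < T:
        dwell = int(rng.integers(30, 71)) if at_a else int(rng.integers(100, 201))
        end = min(t + dwell, T)
        epochs.append((t, end, "locationA" if at_a else "other"))
        t = end
        at_a = not at_a
    return OccupancyTrack(epochs, n_frames=T)


_SCENARIOS = ("control", "NE_0.5h", "NE_4h")


def _scenario_settings(scenario: str, params: GeneratorParams) -> dict:
    """Scenario semantics: retention, gain, infiltration depth, outcome."""
    if scenario == "control":
        return dict(mode="none", q=params.q_remember, g=params.g_remember,
                    diffuseness=params.diffuseness_remember,
                    ne_react=params.ne_reactivation_remember, outcome="remember")
    if scenario == "NE_0.5h":  # effective interference within the consolidation window
        mode = "core" if params.infiltration else "none"
        return dict(mode=mode, q=params.q_forget, g=params.g_forget,
                    diffuseness=params.diffuseness_forget,
                    ne_react=params.ne_reactivation_forget, outcome="forget")
    if scenario == "NE_4h":  # interference after consolidation: peripheral, harmless
        mode = "peripheral" if params.infiltration else "none"
        return dict(mode=mode, q=params.q_remember, g=params.g_remember,
                    diffuseness=params.diffuseness_remember,
                    ne_react=params.ne_reactivation_remember, outcome="remember")
    raise ValueError(f"unknown scenario {scenario!r}; expected one of {_SCENARIOS}")


def simulate_animal(
    scenario: str,
    seed: int,
    params: GeneratorParams | None = None,
    animal_id: str | None = None,
    q: float | None = None,
    g: float | None = None,
    diffuseness: float | None = None,
    sessions: tuple = SESSIONS,
) -> SessionBundle:
    """Simulate one animal's full session bundle under a scenario.

    ``q``, ``g`` and ``diffuseness`` override the scenario's retention, gain
    and loss-diffuseness (used both for parameter-recovery experiments and for
    per-animal cohort variability).
    """
    params = params or GeneratorParams()
    cfg = _scenario_settings(scenario, params)
    gt = make_ground_truth(
        params.n_core,
        params.n_periph,
        params.n_background,
        params.n_ne,
        seed=seed,
        p_cc=params.p_cc,
        p_cp=params.p_cp,
        p_pp=params.p_pp,
        infiltration_mode=cfg["mode"],
        attachments=params.attachments,
        q=cfg["q"] if q is None else q,
        g=cfg["g"] if g is None else g,
        loss_diffuseness=cfg["diffuseness"] if diffuseness is None else diffuseness,
        maturation_m=params.maturation_m,
        reactivation_base=params.reactivation_base,
        ne_reactivation=cfg["ne_react"],
        lambda_bg=params.lambda_bg,
        lambda_edge=params.lambda_edge,
        window_len=params.window_len,
        offset_span=params.offset_span,
    )
    rasters = {}
    for k, sess in enumerate(SESSIONS):
        if sess not in sessions:
            continue
        sess_seed = int(np.random.SeedSequence([seed, 211 + k]).generate_state(1)[0] % (2**31))
        rasters[sess] = simulate_session(
            gt, sess, T=params.n_frames, frame_period=params.frame_period, seed=sess_seed
        )
    regmap = RegistrationMap.identity(gt.node_ids, list(rasters))
    occ_rng = np.random.default_rng(np.random.SeedSequence([seed, _SALT_OCC]))
    occupancy = {
        sess: _occupancy_track(params.n_frames, occ_rng)
        for sess in ("training", "test")
        if sess in rasters
    }
    aid = animal_id or f"{scenario}_{seed}"
    record = AnimalRecord(aid, group=scenario, outcome=cfg["outcome"])
    return SessionBundle(
        animal_id=aid,
        scenario=scenario,
        rasters=rasters,
        regmap=regmap,
        occupancy=occupancy,
        ground_truth=gt,
        record=record,
    )


def animal_seed(master_seed: int, index: int) -> int:
    """Documented master-seed -> per-animal seed derivation."""
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0] % (2**31))


def simulate_cohort(
    n_per_group: int,
    seed: int,
    params: GeneratorParams | None = None,
    scenarios: tuple = _SCENARIOS,
    sessions: tuple = SESSIONS,
) -> list:
    """Independent animals per scenario with per-animal seeds from the master.

    Per-animal retention and gain are drawn around the scenario means
    (sd = sigma_q / sigma_g, truncated to (0.02, 0.98)), providing the
    within-group variability against which the group effect size is defined.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    params = params or GeneratorParams()
    bundles = []
    idx = 0
    for scenario in scenarios:
        cfg = _scenario_settings(scenario, params)
        for j in range(n_per_group):
            a_seed = animal_seed(seed, idx)
            draw = np.random.default_rng(np.random.SeedSequence([seed, 997, idx]))
            rho = params.rho_qg
            e_i, z1, z2, z3 = draw.standard_normal(4)  # e_i = shared expressivity factor
            q_i = cfg["q"] + params.sigma_q * (np.sqrt(rho) * e_i + np.sqrt(1 - rho) * z1)
            g_i = cfg["g"] + params.sigma_g * (np.sqrt(rho) * e_i + np.sqrt(1 - rho) * z2)
            q_i = float(np.clip(q_i, 0.02, 0.98))
            g_i = float(np.clip(g_i, 0.02, 0.98))
            d_i = float(np.clip(cfg["diffuseness"] + params.sigma_diffuseness * z3, 0.0, 1.0))
            bundles.append(
                simulate_animal(
                    scenario,
                    seed=a_seed,
                    params=params,
                    animal_id=f"{scenario}_{j}",
                    q=q_i,
                    g=g_i,
                    diffuseness=d_i,
                    sessions=sessions,
                )
            )
            idx += 1
    return bundles
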
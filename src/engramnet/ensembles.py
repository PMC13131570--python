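"""Node-level ensemble definitions and reactivation statistics.

An "ensemble" here is a labelled set of neuron ids: the neurons active during
learning (the putative engram), neurons active only during novelty exploration
(NE-specific, candidate infiltrators), or neurons gated to a behavioural
location. Reactivation of an ensemble in a later session is the fraction of
its members active again there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rasters import EventRaster, OccupancyTrack, RegistrationMap, align_pair

__all__ = [
    "NeuronSet",
    "active_set",
    "reactivation_fraction",
    "ne_specific",
    "gate_raster",
    "overlap_stats",
]


@dataclass
class NeuronSet:
    """A labelled set of global neuron ids, with optional per-id provenance."""

    ids: set
    label: str = ""
    origin: dict = field(default_factory=dict)  # id -> provenance tag

    def __post_init__(self) -> None:
        self.ids = set(self.ids)

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, x) -> bool:
        return x in self.ids

    def write_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# label: {self.label}\n")
            fh.write("neuron_id\n")
            for nid in sorted(self.ids, key=str):
                fh.write(f"{nid}\n")


def active_set(raster: EventRaster, min_events: int = 1, label: str = "") -> NeuronSet:
    """Neurons whose total event count over the session is >= min_events."""
    if min_events < 1:
        raise ValueError("min_events must be >= 1")
    totals = raster.total_events()
    ids = {nid for nid, tot in zip(raster.neuron_ids, totals) if tot >= min_events}
    return NeuronSet(ids, label=label or f"active(>={min_events}) in {raster.session_id}")


def reactivation_fraction(reference: NeuronSet, raster: EventRaster, min_events: int = 1) -> float:
    """Fraction of a reference ensemble active (>= min_events) in *raster*.

    The raster must already be indexed on global ids covering the reference
    (i.e. aligned); reference members absent from the raster's columns count
    as not reactivated.
    """
    if len(reference) == 0:
        raise ValueError("reference ensemble is empty; reactivation undefined")
    act = active_set(raster, min_events=min_events)
    return len(reference.ids & act.ids) / len(reference)


def ne_specific(
    ne_raster: EventRaster,
    training_raster: EventRaster,
    regmap: RegistrationMap,
    min_ne_events: int = 1,
    max_training_events: int = 0,
) -> NeuronSet:
    """Neurons preferentially active during novelty exploration but silent in training.

    Returns global ids that are active (>= min_ne_events) in the NE session and
    whose registered training counterpart has <= max_training_events events,
    plus NE-active ids with no registered training counterpart. The ``origin``
    dict distinguishes the two cases (``registered_silent`` vs ``unregistered``).
    """
    ne_map = regmap.session_map(ne_raster.session_id)
    tr_map = regmap.session_map(training_raster.session_id)
    if not ne_map:
        raise ValueError(f"session {ne_raster.session_id!r} not in registration map")
    ne_totals = ne_raster.total_events()
    tr_totals = training_raster.total_events()
    ne_active_gids = {
        g for g, j in ne_map.items() if j < ne_raster.n_neurons and ne_totals[j] >= min_ne_events
    }
    ids: set = set()
    origin: dict = {}
    for g in ne_active_gids:
        if g in tr_map and tr_map[g] < training_raster.n_neurons:
            if tr_totals[tr_map[g]] <= max_training_events:
                ids.add(g)
                origin[g] = "registered_silent"
        else:
            ids.add(g)
            origin[g] = "unregistered"
    return NeuronSet(ids, label="NE-specific", origin=origin)


def gate_raster(
    raster: EventRaster, occupancy: OccupancyTrack, label: str, lead_frames: int = 10
) -> EventRaster:
    """Zero all events outside the labelled epochs and their 1-s lead window.

    The gate is the union over labelled epochs of ``[start - lead_frames, end)``,
    clipped at frame 0 — events immediately preceding or during occupancy.
    """
    if occupancy.n_frames != raster.n_frames:
        raise ValueError("occupancy track and raster must cover the same frames")
    mask = occupancy.frames_for(label, lead_frames=lead_frames)
    gated = np.where(mask[:, None], raster.counts, 0)
    return EventRaster(
        gated, frame_period=raster.frame_period,
        session_id=raster.session_id, neuron_ids=raster.neuron_ids,
    )


def overlap_stats(a: NeuronSet, b: NeuronSet, universe_size: int) -> tuple[float, float, float]:
    """Relative sizes and overlap of two ensembles against a common universe."""
    if universe_size <= 0:
        raise ValueError("universe_size must be positive")
    if universe_size < len(a.ids | b.ids):
        raise ValueError("universe smaller than the union of the two sets")
    return (
        len(a) / universe_size,
        len(b) / universe_size,
        len(a.ids & b.ids) / universe_size,
    )
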
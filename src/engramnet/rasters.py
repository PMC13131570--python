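"""Event rasters, cross-session registration, occupancy epochs, and animal records.

The raster is the pipeline's primitive: a frames-by-neurons matrix of calcium
event counts at a fixed frame period (default 0.1 s, i.e. 10 Hz event bins).
An entry > 0 means the neuron emitted at least one detected event in that
frame; counts above 1 are retained but every downstream "active" predicate
thresholds at >= 1 event.

Frames are 0-based and epoch intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EventRaster",
    "RegistrationMap",
    "OccupancyTrack",
    "AnimalRecord",
    "read_event_table",
    "write_event_table",
    "read_occupancy",
    "write_occupancy",
    "read_registration",
    "write_registration",
    "read_animal_records",
    "write_animal_records",
    "align_pair",
]

DEFAULT_FRAME_PERIOD = 0.1  # seconds per frame: 10 frames = the 1-s coactivity window


@dataclass
class EventRaster:
    """Neuron-by-time event-count matrix for one imaging session.

    Parameters
    ----------
    counts
        Integer array of shape (T, N): rows are frames, columns neurons.
    frame_period
        Seconds per frame (> 0).
    session_id
        Free-text session identifier (e.g. ``training``, ``test``, ``NE``).
    neuron_ids
        Ordered per-session neuron identifiers, one per column.
    """

    counts: np.ndarray
    frame_period: float = DEFAULT_FRAME_PERIOD
    session_id: str = "other"
    neuron_ids: Sequence = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D (frames x neurons) array")
        if self.counts.shape[0] < 1 or self.counts.shape[1] < 1:
            raise ValueError("raster needs at least one frame and one neuron")
        if np.any(self.counts < 0):
            raise ValueError("event counts must be non-negative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("event counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if self.frame_period <= 0:
            raise ValueError("frame_period must be positive")
        if self.neuron_ids is None:
            self.neuron_ids = list(range(self.counts.shape[1]))
        else:
            self.neuron_ids = list(self.neuron_ids)
        if len(self.neuron_ids) != self.counts.shape[1]:
            raise ValueError("neuron_ids length must equal number of columns")
        if len(set(self.neuron_ids)) != len(self.neuron_ids):
            raise ValueError("neuron_ids must be unique")

    @property
    def n_frames(self) -> int:
        return int(self.counts.shape[0])

    @property
    def n_neurons(self) -> int:
        return int(self.counts.shape[1])

    @property
    def duration(self) -> float:
        """Session duration in seconds (T x frame_period)."""
        return self.n_frames * self.frame_period

    def total_events(self) -> np.ndarray:
        """Per-neuron total event count over the session."""
        return self.counts.sum(axis=0)

    def column_index(self) -> dict:
        return {nid: j for j, nid in enumerate(self.neuron_ids)}


@dataclass
class RegistrationMap:
    """Cross-session cell registration: global neuron id <-> per-session index.

    The mapping may be partial — a global id need not be present in every
    session. Registration is consumed as an input; computing it from imaging
    data is out of scope.
    """

    entries: list  # (global_id, session_id, session_index) triples

    def __post_init__(self) -> None:
        self.entries = [(g, str(s), int(i)) for g, s, i in self.entries]
        seen_idx: set = set()
        seen_gid: set = set()
        for g, s, i in self.entries:
            if (s, i) in seen_idx:
                raise ValueError(f"session index {i} appears twice in session {s!r}")
            if (g, s) in seen_gid:
                raise ValueError(f"global id {g!r} maps to two indices in session {s!r}")
            seen_idx.add((s, i))
            seen_gid.add((g, s))

    @property
    def sessions(self) -> list:
        out: list = []
        for _, s, _ in self.entries:
            if s not in out:
                out.append(s)
        return out

    def session_map(self, session_id: str) -> dict:
        """global_id -> session_index for one session."""
        return {g: i for g, s, i in self.entries if s == session_id}

    @classmethod
    def identity(cls, ids: Sequence, sessions: Sequence) -> "RegistrationMap":
        """Every id registered at its own position in every session."""
        ids = list(ids)
        return cls([(g, s, j) for s in sessions for j, g in enumerate(ids)])


@dataclass
class OccupancyTrack:
    """Labelled behavioural epochs as half-open frame intervals [start, end)."""

    epochs: list  # (start_frame, end_frame, label)
    n_frames: int

    def __post_init__(self) -> None:
        self.epochs = [(int(a), int(b), str(lab)) for a, b, lab in self.epochs]
        for a, b, lab in self.epochs:
            if not (0 <= a < b <= self.n_frames):
                raise ValueError(
                    f"epoch ({a},{b},{lab!r}) violates 0 <= start < end <= {self.n_frames}"
                )
        by_label: dict = {}
        for a, b, lab in self.epochs:
            by_label.setdefault(lab, []).append((a, b))
        for lab, ivals in by_label.items():
            ivals.sort()
            for (a1, b1), (a2, _) in zip(ivals, ivals[1:]):
                if a2 < b1:
                    raise ValueError(f"epochs with label {lab!r} overlap: ({a1},{b1}) and start {a2}")

    def labels(self) -> set:
        return {lab for _, _, lab in self.epochs}

    def frames_for(self, label: str, lead_frames: int = 0) -> np.ndarray:
        """Boolean mask of frames inside (or within lead_frames before) the epochs."""
        if label not in self.labels():
            raise ValueError(f"label {label!r} not present in occupancy track")
        mask = np.zeros(self.n_frames, dtype=bool)
        for a, b, lab in self.epochs:
            if lab == label:
                mask[max(0, a - lead_frames) : b] = True
        return mask


@dataclass
class AnimalRecord:
    """Per-animal grouping and behavioural outcome."""

    animal_id: str
    group: str = "custom"  # control | NE_0.5h | NE_4h | custom
    outcome: str | None = None  # "remember" | "forget"
    discrimination_ratio: float | None = None

    def __post_init__(self) -> None:
        if self.outcome is not None and self.outcome not in ("remember", "forget"):
            raise ValueError("outcome must be 'remember', 'forget', or None")


# ---------------------------------------------------------------------------
# readers / writers (sparse CSV event tables, occupancy, registration, records)
# ---------------------------------------------------------------------------

def read_event_table(
    path,
    frame_period: float = DEFAULT_FRAME_PERIOD,
    n_frames: int | None = None,
    neuron_ids: Sequence | None = None,
    session_id: str = "other",
) -> EventRaster:
    """Read a sparse delimited event table (header ``frame,neuron_id,count``).

    Missing cells are zero. If *n_frames* is absent, T = max frame + 1.
    Duplicate (frame, neuron) rows, negative counts, and frames beyond
    *n_frames* are rejected with the offending row named.
    """
    df = pd.read_csv(path)
    required = {"frame", "neuron_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"event table must have columns {sorted(required)}, got {list(df.columns)}")
    if "count" not in df.columns:
        df["count"] = 1
    ids = list(neuron_ids) if neuron_ids is not None else sorted(df["neuron_id"].unique().tolist())
    if not ids:
        raise ValueError("event table has no neurons and no neuron_ids were supplied")
    if n_frames is None:
        if df.empty:
            raise ValueError("cannot infer n_frames from an empty table")
        n_frames = int(df["frame"].max()) + 1
    col = {nid: j for j, nid in enumerate(ids)}
    counts = np.zeros((int(n_frames), len(ids)), dtype=np.int64)
    seen: set = set()
    for row in df.itertuples(index=False):
        f, nid, c = int(row.frame), row.neuron_id, int(row.count)
        if c < 0:
            raise ValueError(f"negative count in row (frame={f}, neuron_id={nid!r}, count={c})")
        if f < 0 or f >= n_frames:
            raise ValueError(f"frame out of range in row (frame={f}, neuron_id={nid!r}): n_frames={n_frames}")
        if nid not in col:
            raise ValueError(f"neuron_id {nid!r} in row (frame={f}) not in supplied neuron_ids")
        if (f, nid) in seen:
            raise ValueError(f"duplicate entry for (frame={f}, neuron_id={nid!r})")
        seen.add((f, nid))
        counts[f, col[nid]] = c
    return EventRaster(counts, frame_period=frame_period, session_id=session_id, neuron_ids=ids)


def write_event_table(raster: EventRaster, path) -> None:
    """Write only the nonzero cells as ``frame,neuron_id,count`` rows."""
    rows, cols = np.nonzero(raster.counts)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["frame", "neuron_id", "count"])
        for f, j in zip(rows.tolist(), cols.tolist()):
            w.writerow([f, raster.neuron_ids[j], int(raster.counts[f, j])])


def read_occupancy(path, n_frames: int) -> OccupancyTrack:
    df = pd.read_csv(path)
    need = {"start_frame", "end_frame", "label"}
    if not need.issubset(df.columns):
        raise ValueError(f"occupancy table must have columns {sorted(need)}")
    epochs = [
        (int(r.start_frame), int(r.end_frame), str(r.label)) for r in df.itertuples(index=False)
    ]
    return OccupancyTrack(epochs, n_frames=n_frames)


def write_occupancy(track: OccupancyTrack, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["start_frame", "end_frame", "label"])
        for a, b, lab in track.epochs:
            w.writerow([a, b, lab])


def read_registration(path) -> RegistrationMap:
    df = pd.read_csv(path)
    need = {"global_id", "session_id", "session_index"}
    if not need.issubset(df.columns):
        raise ValueError(f"registration map must have columns {sorted(need)}")
    return RegistrationMap(
        [(r.global_id, str(r.session_id), int(r.session_index)) for r in df.itertuples(index=False)]
    )


def write_registration(regmap: RegistrationMap, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["global_id", "session_id", "session_index"])
        for g, s, i in regmap.entries:
            w.writerow([g, s, i])


def read_animal_records(path) -> list:
    df = pd.read_csv(path)
    need = {"animal_id", "group", "outcome"}
    if not need.issubset(df.columns):
        raise ValueError(f"animal record table must have columns {sorted(need)}")
    out = []
    for r in df.itertuples(index=False):
        dr = getattr(r, "discrimination_ratio", None)
        dr = None if dr is None or (isinstance(dr, float) and np.isnan(dr)) else float(dr)
        out.append(
            AnimalRecord(str(r.animal_id), group=str(r.group), outcome=str(r.outcome), discrimination_ratio=dr)
        )
    return out


def write_animal_records(records: Sequence[AnimalRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["animal_id", "group", "outcome", "discrimination_ratio"])
        for r in records:
            w.writerow([r.animal_id, r.group, r.outcome, "" if r.discrimination_ratio is None else r.discrimination_ratio])


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def align_pair(
    raster_a: EventRaster, raster_b: EventRaster, regmap: RegistrationMap
) -> tuple[EventRaster, EventRaster, list]:
    """Re-index two sessions onto the global ids registered in both.

    Returns the two rasters restricted to the shared neurons (columns in the
    same order, sorted by global id) and the ordered shared id list. Neurons
    registered in only one session are dropped rather than zero-filled — a
    neuron that was not recorded is not the same as a silent one.
    """
    map_a = regmap.session_map(raster_a.session_id)
    map_b = regmap.session_map(raster_b.session_id)
    if not map_a or not map_b:
        raise ValueError(
            f"both sessions ({raster_a.session_id!r}, {raster_b.session_id!r}) must appear in the registration map"
        )
    shared = sorted(set(map_a) & set(map_b), key=_sort_key)
    shared = [g for g in shared if map_a[g] < raster_a.n_neurons and map_b[g] < raster_b.n_neurons]
    if not shared:
        raise ValueError("no neurons are registered in both sessions; comparison undefined")
    cols_a = [map_a[g] for g in shared]
    cols_b = [map_b[g] for g in shared]
    out_a = EventRaster(
        raster_a.counts[:, cols_a], frame_period=raster_a.frame_period,
        session_id=raster_a.session_id, neuron_ids=shared,
    )
    out_b = EventRaster(
        raster_b.counts[:, cols_b], frame_period=raster_b.frame_period,
        session_id=raster_b.session_id, neuron_ids=shared,
    )
    return out_a, out_b, shared


def _sort_key(x):
    # deterministic ordering for possibly mixed-type ids
    return (str(type(x).__name__), x) if not isinstance(x, str) else ("str", x)
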
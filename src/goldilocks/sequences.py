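"""Design of 3-box / 3-object visual-event sequences.

A trial shows three boxes at distinct screen locations, each concealing one
unique object. Events are object pop-ups: 750 ms out, 750 ms back in, with
no overlap or delay, so event onsets tile the trial at ``duration_ms``
(default 1500 ms) intervals. Object identity order is the only
surprisal-relevant property; box geometry matters solely for gaze scoring.

`generate_sequence_set` builds the stimulus set: a pool of candidate
sequences with deliberately varied object statistics is scored by the
unigram ideal observer, each candidate is summarized by (mean, SD, max) of
its surprisal trace, and a greedy maximin rule keeps the ``n_sequences``
candidates whose summaries are maximally spread out. This is a concrete,
reproducible stand-in for the published stimuli's stated goal of maximizing
the spread of the sequences' theoretical information properties; the exact
published generation procedure is not available, so treat the selected set
as statistically comparable rather than identical stimuli.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "EventToken",
    "SequenceSpec",
    "SequenceSet",
    "BoxGeometry",
    "sample_box_geometry",
    "make_sequence",
    "random_sequence",
    "candidate_pool",
    "select_maximin",
    "generate_sequence_set",
    "sequence_summary",
    "dispersion_score",
    "save_sequence_set",
    "load_sequence_set",
]

DEFAULT_EVENT_DURATION_MS = 1500  # 750 ms pop-up + 750 ms retreat
DEFAULT_SCREEN = (1920, 1080)
DEFAULT_AOI_RADIUS_PX = 150.0


@dataclass(frozen=True)
class EventToken:
    index: int
    object_id: int
    location_id: int
    onset_ms: int
    duration_ms: int = DEFAULT_EVENT_DURATION_MS


@dataclass(frozen=True)
class BoxGeometry:
    """Screen placement of the boxes and the filler fixation point.

    Box centers live on a jittered 3x3 grid with the central cell reserved
    for the between-event fixation point, which guarantees every center is
    well clear of all AOIs.
    """

    box_centers: tuple[tuple[float, float], ...]
    screen: tuple[int, int] = DEFAULT_SCREEN
    aoi_radius_px: float = DEFAULT_AOI_RADIUS_PX

    def __post_init__(self) -> None:
        centers = np.asarray(self.box_centers, dtype=float)
        if centers.ndim != 2 or centers.shape[1] != 2:
            raise ValueError("box_centers must be a list of (x, y) pairs")
        if len(centers) != len({tuple(c) for c in self.box_centers}):
            raise ValueError("box centers must be distinct")
        d = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() < 2 * self.aoi_radius_px:
            raise ValueError(
                f"box centers closer than 2 x AOI radius ({2 * self.aoi_radius_px} px): AOIs overlap"
            )

    @property
    def n_locations(self) -> int:
        return len(self.box_centers)

    @property
    def filler_point(self) -> tuple[float, float]:
        return (self.screen[0] / 2.0, self.screen[1] / 2.0)


def sample_box_geometry(
    rng: np.random.Generator,
    n_boxes: int = 3,
    screen: tuple[int, int] = DEFAULT_SCREEN,
    aoi_radius_px: float = DEFAULT_AOI_RADIUS_PX,
    jitter_px: float = 20.0,
) -> BoxGeometry:
    """Place boxes on randomly chosen distinct cells of a jittered 3x3 grid.

    The central grid cell is excluded (kept for the fixation point) and the
    grid spacing guarantees a minimum pairwise separation of 2 x AOI radius
    even at maximum jitter.
    """
    w, h = screen
    xs = np.array([0.25, 0.5, 0.75]) * w
    ys = np.array([0.18, 0.5, 0.82]) * h
    cells = [(x, y) for y in ys for x in xs]
    cells.remove((0.5 * w, 0.5 * h))
    idx = rng.choice(len(cells), size=n_boxes, replace=False)
    centers = []
    for i in idx:
        cx, cy = cells[i]
        centers.append(
            (
                float(cx + rng.uniform(-jitter_px, jitter_px)),
                float(cy + rng.uniform(-jitter_px, jitter_px)),
            )
        )
    return BoxGeometry(tuple(centers), screen=screen, aoi_radius_px=aoi_radius_px)


@dataclass(frozen=True)
class SequenceSpec:
    """One stimulus sequence: object order, binding, and geometry."""

    sequence_id: str
    n_objects: int
    geometry: BoxGeometry
    events: tuple[EventToken, ...]
    object_descriptors: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.events:
            raise ValueError("a sequence must contain at least one event")
        if self.geometry.n_locations < self.n_objects:
            raise ValueError("need at least as many box locations as objects")
        binding: dict[int, int] = {}
        expected_onset = 0
        for i, ev in enumerate(self.events):
            if ev.index != i:
                raise ValueError("event indices must be consecutive from 0")
            if not 0 <= ev.object_id < self.n_objects:
                raise ValueError(f"object id {ev.object_id} out of range [0, {self.n_objects})")
            if not 0 <= ev.location_id < self.geometry.n_locations:
                raise ValueError("location id out of range")
            if ev.onset_ms != expected_onset:
                raise ValueError("events must tile the trial without overlap or delay")
            expected_onset += ev.duration_ms
            prev = binding.setdefault(ev.object_id, ev.location_id)
            if prev != ev.location_id:
                raise ValueError("object-to-box binding must be constant within a sequence")
        if len(set(binding.values())) != len(binding):
            raise ValueError("object-to-box binding must be one-to-one")

    @property
    def object_ids(self) -> np.ndarray:
        return np.array([ev.object_id for ev in self.events], dtype=int)

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def duration_ms(self) -> int:
        last = self.events[-1]
        return last.onset_ms + last.duration_ms

    def event_center(self, event: EventToken) -> tuple[float, float]:
        return self.geometry.box_centers[event.location_id]


@dataclass(frozen=True)
class SequenceSet:
    sequences: tuple[SequenceSpec, ...]
    generation_seed: int
    dispersion_score: float

    def __post_init__(self) -> None:
        ids = [s.sequence_id for s in self.sequences]
        if len(ids) != len(set(ids)):
            raise ValueError("sequence ids must be unique")
        if self.dispersion_score < 0:
            raise ValueError("dispersion score must be non-negative")

    def __len__(self) -> int:
        return len(self.sequences)

    def by_id(self) -> dict[str, SequenceSpec]:
        return {s.sequence_id: s for s in self.sequences}


def make_sequence(
    event_object_ids: Sequence[int],
    geometry: BoxGeometry,
    duration_ms: int = DEFAULT_EVENT_DURATION_MS,
    sequence_id: str = "seq",
    n_objects: int = 3,
    location_map: Sequence[int] | None = None,
) -> SequenceSpec:
    """Build a sequence with consecutive onsets 0, d, 2d, ...

    ``location_map`` gives the box index for each object (identity by
    default); it must be a bijection onto distinct locations.
    """
    ids = list(event_object_ids)
    if not ids:
        raise ValueError("event_object_ids must be non-empty")
    if any(not 0 <= i < n_objects for i in ids):
        raise ValueError(f"object ids must lie in [0, {n_objects})")
    if location_map is None:
        location_map = list(range(n_objects))
    events = tuple(
        EventToken(
            index=i,
            object_id=int(obj),
            location_id=int(location_map[int(obj)]),
            onset_ms=i * int(duration_ms),
            duration_ms=int(duration_ms),
        )
        for i, obj in enumerate(ids)
    )
    return SequenceSpec(sequence_id=sequence_id, n_objects=n_objects, geometry=geometry, events=events)


def random_sequence(
    length: int,
    n_objects: int = 3,
    rng: np.random.Generator | int | None = None,
    bias: Sequence[float] | None = None,
    geometry: BoxGeometry | None = None,
    duration_ms: int = DEFAULT_EVENT_DURATION_MS,
    sequence_id: str = "seq",
) -> SequenceSpec:
    """I.i.d. random object order, optionally biased by per-object weights."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(rng)
    if bias is None:
        p = np.full(n_objects, 1.0 / n_objects)
    else:
        p = np.asarray(bias, dtype=float)
        if p.shape != (n_objects,) or np.any(p < 0) or p.sum() <= 0:
            raise ValueError("bias must be non-negative per-object weights, not all zero")
        p = p / p.sum()
    if geometry is None:
        geometry = sample_box_geometry(rng, n_boxes=n_objects)
    ids = rng.choice(n_objects, size=length, p=p)
    return make_sequence(ids, geometry, duration_ms=duration_ms, sequence_id=sequence_id, n_objects=n_objects)


def sequence_summary(seq: SequenceSpec, alpha: float = 1.0) -> np.ndarray:
    """(mean, SD, max) of the unigram surprisal trace — the selection features."""
    from .ideal_observer import unigram_surprisal_trace

    s = unigram_surprisal_trace(seq, alpha=alpha)
    return np.array([s.mean(), s.std(), s.max()])


def dispersion_score(summaries: np.ndarray) -> float:
    """Mean nearest-neighbour Euclidean distance among summary vectors.

    This is the quantity the greedy maximin selection pushes up: large values
    mean the set's information profiles are well spread out.
    """
    x = np.asarray(summaries, dtype=float)
    if len(x) < 2:
        return 0.0
    d = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    return float(d.min(axis=1).mean())


def _greedy_maximin(summaries: np.ndarray, n_select: int) -> list[int]:
    """Pick n_select rows maximizing the minimum distance to already-picked rows.

    Seeded with the point farthest from the pool centroid (ties broken by
    lowest index), which makes selection a pure function of the pool.
    """
    x = np.asarray(summaries, dtype=float)
    centroid = x.mean(axis=0)
    d0 = np.linalg.norm(x - centroid, axis=1)
    first = int(np.argmax(d0))  # argmax takes the lowest index on ties
    chosen = [first]
    mind = np.linalg.norm(x - x[first], axis=1)
    for _ in range(n_select - 1):
        mind[chosen] = -np.inf
        nxt = int(np.argmax(mind))
        chosen.append(nxt)
        mind = np.minimum(mind, np.linalg.norm(x - x[nxt], axis=1))
    return chosen


def candidate_pool(
    candidate_pool_size: int,
    length: int,
    rng: np.random.Generator | int | None = None,
    n_objects: int = 3,
    duration_ms: int = DEFAULT_EVENT_DURATION_MS,
) -> list[SequenceSpec]:
    """Candidate sequences with per-candidate Dirichlet(1,..,1) object weights,
    so pop-up probabilities genuinely vary across the pool."""
    rng = np.random.default_rng(rng)
    pool = []
    for i in range(candidate_pool_size):
        w = rng.dirichlet(np.ones(n_objects))
        geom = sample_box_geometry(rng, n_boxes=n_objects)
        pool.append(
            random_sequence(
                length,
                n_objects=n_objects,
                rng=rng,
                bias=w,
                geometry=geom,
                duration_ms=duration_ms,
                sequence_id=f"cand{i:04d}",
            )
        )
    return pool


def select_maximin(pool: list[SequenceSpec], n_select: int, alpha: float = 1.0) -> list[int]:
    """Indices of the ``n_select`` pool members whose unigram-surprisal
    summaries are maximally mutually spread (greedy maximin)."""
    if len(pool) < n_select:
        raise ValueError("candidate pool must be at least as large as the requested set")
    summaries = np.array([sequence_summary(s, alpha=alpha) for s in pool])
    return _greedy_maximin(summaries, n_select)


def generate_sequence_set(
    n_sequences: int = 80,
    length: int = 30,
    candidate_pool_size: int = 400,
    rng_seed: int = 0,
    n_objects: int = 3,
    alpha: float = 1.0,
    duration_ms: int = DEFAULT_EVENT_DURATION_MS,
) -> SequenceSet:
    """Generate the stimulus set by maximin selection from a candidate pool."""
    if candidate_pool_size < n_sequences:
        raise ValueError("candidate pool must be at least as large as the requested set")
    rng = np.random.default_rng(rng_seed)
    pool = candidate_pool(candidate_pool_size, length, rng=rng, n_objects=n_objects, duration_ms=duration_ms)
    summaries = np.array([sequence_summary(s, alpha=alpha) for s in pool])
    chosen = _greedy_maximin(summaries, n_sequences)
    selected = []
    for rank, idx in enumerate(chosen):
        src = pool[idx]
        selected.append(
            SequenceSpec(
                sequence_id=f"seq{rank:03d}",
                n_objects=src.n_objects,
                geometry=src.geometry,
                events=src.events,
                object_descriptors=src.object_descriptors,
            )
        )
    score = dispersion_score(summaries[chosen])
    return SequenceSet(tuple(selected), generation_seed=int(rng_seed), dispersion_score=score)


# ---------------------------------------------------------------------------
# JSON round-trip


def _sequence_to_dict(seq: SequenceSpec) -> dict:
    return {
        "sequence_id": seq.sequence_id,
        "n_objects": seq.n_objects,
        "box_centers": [list(c) for c in seq.geometry.box_centers],
        "screen": list(seq.geometry.screen),
        "aoi_radius_px": seq.geometry.aoi_radius_px,
        "object_descriptors": list(seq.object_descriptors),
        "events": [
            {
                "index": ev.index,
                "object_id": ev.object_id,
                "location_id": ev.location_id,
                "onset_ms": ev.onset_ms,
                "duration_ms": ev.duration_ms,
            }
            for ev in seq.events
        ],
    }


def _sequence_from_dict(d: dict) -> SequenceSpec:
    geom = BoxGeometry(
        tuple(tuple(c) for c in d["box_centers"]),
        screen=tuple(d.get("screen", DEFAULT_SCREEN)),
        aoi_radius_px=float(d.get("aoi_radius_px", DEFAULT_AOI_RADIUS_PX)),
    )
    events = tuple(EventToken(**ev) for ev in d["events"])
    return SequenceSpec(
        sequence_id=d["sequence_id"],
        n_objects=int(d["n_objects"]),
        geometry=geom,
        events=events,
        object_descriptors=tuple(d.get("object_descriptors", ())),
    )


def save_sequence_set(sset: SequenceSet, path: str | Path) -> None:
    payload = {
        "generation_seed": sset.generation_seed,
        "dispersion_score": sset.dispersion_score,
        "sequences": [_sequence_to_dict(s) for s in sset.sequences],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_sequence_set(path: str | Path) -> SequenceSet:
    d = json.loads(Path(path).read_text())
    return SequenceSet(
        tuple(_sequence_from_dict(s) for s in d["sequences"]),
        generation_seed=int(d["generation_seed"]),
        dispersion_score=float(d["dispersion_score"]),
    )
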
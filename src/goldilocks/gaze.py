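"""Reduction of raw gaze streams to per-event behavioural measures.

Input is a 1000 Hz gaze sample stream per trial (1 ms spacing, screen
pixels, validity flag). Three measures are extracted per pop-up event:

* **RT** — latency in ms from pop-up onset to the first gaze sample inside
  the event's circular AOI; 0 if gaze is already inside at onset; absent if
  the AOI is never entered during the event window.
* **Predictive-looking** — defined only on an object's *first* appearance:
  was gaze already inside that box's AOI in the pre-onset window (default:
  the single sample at onset − 1 ms)? Absent for later appearances, and at
  event 0, where no pre-onset sample exists.
* **Look-away** — the index of the event containing the start of the first
  run of ≥ 750 consecutive ms (half an event) of off-screen gaze, where
  "off-screen" means outside the screen bounds or track loss. Every event
  after the look-away event is flagged ``included=False`` and its measures
  are censored, mirroring the trial-terminating convention of infant
  look-away paradigms.

Covariates for the controlled regressions are computed alongside: repeat
status (same object as the previous event), the distance in pixels between
the current and previous pop-up box centers (absent at event 0), and the
trial's ordinal position in the session.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .ideal_observer import SurprisalTrace
from .sequences import EventToken, SequenceSpec

__all__ = [
    "GazeTrial",
    "LOOK_AWAY_THRESHOLD_MS",
    "in_aoi",
    "compute_rt",
    "compute_predictive_look",
    "compute_look_away",
    "build_event_table",
    "write_gaze_csv",
    "read_gaze_csv",
]

LOOK_AWAY_THRESHOLD_MS = 750  # 50% of the 1500 ms pop-up event


@dataclass
class GazeTrial:
    """One subject x trial gaze stream at 1 ms resolution."""

    subject_id: str
    trial_id: str
    trial_number: int
    sequence_id: str
    t_ms: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    valid: np.ndarray
    screen_bounds: tuple[float, float, float, float] = (0.0, 0.0, 1920.0, 1080.0)
    aoi_radius_px: float = 150.0

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=np.int64)
        self.x_px = np.asarray(self.x_px, dtype=float)
        self.y_px = np.asarray(self.y_px, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.t_ms)
        if not (len(self.x_px) == len(self.y_px) == len(self.valid) == n):
            raise ValueError("sample arrays must have equal length")
        if n and np.any(np.diff(self.t_ms) != 1):
            raise ValueError("samples must be strictly increasing at 1 ms spacing (1000 Hz)")
        x0, y0, x1, y1 = self.screen_bounds
        if x1 <= x0 or y1 <= y0:
            raise ValueError("screen bounds are degenerate")

    def offscreen_mask(self) -> np.ndarray:
        """Off-screen or track-lost samples."""
        x0, y0, x1, y1 = self.screen_bounds
        outside = (self.x_px < x0) | (self.x_px > x1) | (self.y_px < y0) | (self.y_px > y1)
        return outside | ~self.valid


def in_aoi(
    x: np.ndarray | float,
    y: np.ndarray | float,
    valid: np.ndarray | bool,
    center: tuple[float, float],
    radius: float,
) -> np.ndarray | bool:
    """Boundary-inclusive circular AOI test; invalid samples never count."""
    if radius <= 0:
        raise ValueError("AOI radius must be positive")
    d2 = (np.asarray(x) - center[0]) ** 2 + (np.asarray(y) - center[1]) ** 2
    return (d2 <= radius**2) & np.asarray(valid, dtype=bool)


def _event_window(trial: GazeTrial, event: EventToken) -> slice:
    # sample index == t_ms because streams start at t=0 with 1 ms spacing
    t0 = int(trial.t_ms[0])
    lo = max(event.onset_ms - t0, 0)
    hi = min(event.onset_ms + event.duration_ms - t0, len(trial.t_ms))
    return slice(lo, hi)


def compute_rt(
    trial: GazeTrial,
    seq: SequenceSpec,
    event: EventToken,
    min_dwell_ms: int = 0,
) -> float | None:
    """Latency from pop-up onset to first AOI entry, or None if never entered.

    ``min_dwell_ms`` optionally requires the gaze to stay inside the AOI for
    that many further consecutive ms before the entry counts (default 0:
    sample-level entry).
    """
    if event.index >= seq.n_events or seq.events[event.index] != event:
        raise ValueError("event does not belong to the trial's sequence")
    win = _event_window(trial, event)
    center = seq.event_center(event)
    mask = in_aoi(trial.x_px[win], trial.y_px[win], trial.valid[win], center, trial.aoi_radius_px)
    if min_dwell_ms > 0 and mask.any():
        # entry = start of first run of length min_dwell_ms + 1
        run = np.convolve(mask.astype(int), np.ones(min_dwell_ms + 1, dtype=int), mode="valid")
        hits = np.flatnonzero(run == min_dwell_ms + 1)
        return float(hits[0]) if hits.size else None
    hits = np.flatnonzero(mask)
    if hits.size == 0:
        return None
    return float(hits[0])


def _first_appearance_indices(seq: SequenceSpec) -> set[int]:
    seen: set[int] = set()
    firsts: set[int] = set()
    for ev in seq.events:
        if ev.object_id not in seen:
            seen.add(ev.object_id)
            firsts.add(ev.index)
    return firsts


def compute_predictive_look(
    trial: GazeTrial,
    seq: SequenceSpec,
    event: EventToken,
    pre_window_ms: int = 1,
) -> bool | None:
    """Was gaze already on the box before its object's first pop-up?

    Returns None (undefined) for repeat appearances and for event 0. True
    iff every sample in [onset - pre_window_ms, onset) lies inside the
    event's AOI.
    """
    if event.index >= seq.n_events or seq.events[event.index] != event:
        raise ValueError("event does not belong to the trial's sequence")
    if event.index not in _first_appearance_indices(seq) or event.index == 0:
        return None
    t0 = int(trial.t_ms[0])
    lo = event.onset_ms - pre_window_ms - t0
    hi = event.onset_ms - t0
    if lo < 0:
        return None
    center = seq.event_center(event)
    win = slice(lo, hi)
    mask = in_aoi(trial.x_px[win], trial.y_px[win], trial.valid[win], center, trial.aoi_radius_px)
    return bool(np.all(mask))


def compute_look_away(
    trial: GazeTrial,
    seq: SequenceSpec,
    threshold_ms: int = LOOK_AWAY_THRESHOLD_MS,
) -> int | None:
    """Event index containing the start of the first >= threshold off-screen run."""
    off = trial.offscreen_mask()
    if not off.any():
        return None
    # run-length encode the boolean stream
    change = np.flatnonzero(np.diff(off.astype(np.int8)))
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [len(off)]))
    for s, e in zip(starts, ends):
        if off[s] and (e - s) >= threshold_ms:
            t_start = int(trial.t_ms[s])
            onsets = np.array([ev.onset_ms for ev in seq.events])
            idx = int(np.searchsorted(onsets, t_start, side="right") - 1)
            if idx < 0 or t_start >= seq.events[idx].onset_ms + seq.events[idx].duration_ms:
                return None  # run starts outside every event window
            return idx
    return None


def trial_measures(
    trial: GazeTrial,
    seq: SequenceSpec,
    pre_window_ms: int = 1,
    min_dwell_ms: int = 0,
    look_away_threshold_ms: int = LOOK_AWAY_THRESHOLD_MS,
) -> pd.DataFrame:
    """Per-event measures + covariates for a single trial.

    Measures of events after the look-away event are censored to NA and
    flagged ``included=False``.
    """
    la_event = compute_look_away(trial, seq, threshold_ms=look_away_threshold_ms)
    rows = []
    prev_ev: EventToken | None = None
    for ev in seq.events:
        included = la_event is None or ev.index <= la_event
        rt = compute_rt(trial, seq, ev, min_dwell_ms=min_dwell_ms) if included else None
        pred = compute_predictive_look(trial, seq, ev, pre_window_ms=pre_window_ms) if included else None
        if la_event is not None and ev.index == la_event:
            rt = None  # attention already disengaged within this event
        if prev_ev is None:
            dist = None
            repeat = False
        else:
            c0 = np.asarray(seq.event_center(prev_ev))
            c1 = np.asarray(seq.event_center(ev))
            dist = float(np.linalg.norm(c1 - c0))
            repeat = prev_ev.object_id == ev.object_id
        rows.append(
            {
                "subject_id": trial.subject_id,
                "trial_id": trial.trial_id,
                "trial_number": trial.trial_number,
                "sequence_id": seq.sequence_id,
                "event_index": ev.index,
                "object_id": ev.object_id,
                "rt_ms": rt,
                "predictive_look": pred,
                "look_away": bool(la_event is not None and ev.index == la_event),
                "included": included,
                "is_repeat": repeat,
                "distance_px": dist,
            }
        )
        prev_ev = ev
    df = pd.DataFrame(rows)
    df["rt_ms"] = df["rt_ms"].astype("Float64")
    df["predictive_look"] = df["predictive_look"].astype("boolean")
    df["distance_px"] = df["distance_px"].astype("Float64")
    return df


def build_event_table(
    trials: Iterable[GazeTrial],
    sequences: Mapping[str, SequenceSpec],
    traces: Iterable[SurprisalTrace],
    pre_window_ms: int = 1,
    min_dwell_ms: int = 0,
    look_away_threshold_ms: int = LOOK_AWAY_THRESHOLD_MS,
) -> pd.DataFrame:
    """One row per (trial, event), measures joined with both surprisal traces."""
    trace_by_id = {tr.sequence_id: tr for tr in traces}
    trials = list(trials)
    missing = sorted(
        {t.sequence_id for t in trials if t.sequence_id not in trace_by_id or t.sequence_id not in sequences}
    )
    if missing:
        raise ValueError(f"no surprisal trace / sequence for sequence_ids: {missing}")
    parts = []
    for trial in trials:
        seq = sequences[trial.sequence_id]
        df = trial_measures(
            trial,
            seq,
            pre_window_ms=pre_window_ms,
            min_dwell_ms=min_dwell_ms,
            look_away_threshold_ms=look_away_threshold_ms,
        )
        tr = trace_by_id[trial.sequence_id]
        df["unigram_surprisal_bits"] = tr.unigram[df["event_index"].to_numpy()]
        df["transitional_surprisal_bits"] = tr.transitional[df["event_index"].to_numpy()]
        parts.append(df)
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# CSV round-trip (long format: one row per gaze sample)

GAZE_COLUMNS = ["subject_id", "trial_id", "trial_number", "sequence_id", "t_ms", "x_px", "y_px", "valid"]

EVENT_COLUMNS = [
    "subject_id", "trial_id", "trial_number", "sequence_id", "event_index", "object_id",
    "rt_ms", "predictive_look", "look_away", "included", "is_repeat", "distance_px",
    "unigram_surprisal_bits", "transitional_surprisal_bits",
]


def write_event_csv(table: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in EVENT_COLUMNS if c in table.columns]
    table[cols].to_csv(path, index=False)


def read_event_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["rt_ms"] = df["rt_ms"].astype("Float64")
    df["distance_px"] = df["distance_px"].astype("Float64")
    df["predictive_look"] = df["predictive_look"].map({"True": True, "False": False, True: True, False: False}).astype("boolean")
    for col in ("look_away", "included", "is_repeat"):
        df[col] = df[col].astype(bool)
    return df


def write_gaze_csv(trials: Iterable[GazeTrial], path: str | Path) -> None:
    frames = []
    for tr in trials:
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": tr.subject_id,
                    "trial_id": tr.trial_id,
                    "trial_number": tr.trial_number,
                    "sequence_id": tr.sequence_id,
                    "t_ms": tr.t_ms,
                    "x_px": tr.x_px,
                    "y_px": tr.y_px,
                    "valid": tr.valid.astype(int),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_gaze_csv(
    path: str | Path,
    screen_bounds: tuple[float, float, float, float] = (0.0, 0.0, 1920.0, 1080.0),
    aoi_radius_px: float = 150.0,
) -> list[GazeTrial]:
    df = pd.read_csv(path)
    trials = []
    for (sub, tid), g in df.groupby(["subject_id", "trial_id"], sort=False):
        g = g.sort_values("t_ms")
        trials.append(
            GazeTrial(
                subject_id=str(sub),
                trial_id=str(tid),
                trial_number=int(g["trial_number"].iloc[0]),
                sequence_id=str(g["sequence_id"].iloc[0]),
                t_ms=g["t_ms"].to_numpy(),
                x_px=g["x_px"].to_numpy(),
                y_px=g["y_px"].to_numpy(),
                valid=g["valid"].to_numpy().astype(bool),
                screen_bounds=screen_bounds,
                aoi_radius_px=aoi_radius_px,
            )
        )
    return trials
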
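"""Synthetic gaze agents with known surprisal dependence.

The simulator inverts the analysis chain: given surprisal traces for a
stimulus set, it draws per-event behavioural outcomes from generalized
linear models whose coefficients are known ground truth, then renders 1000
Hz gaze streams that the measurement code recovers *exactly*. That makes the
whole pipeline testable by parameter recovery with no recorded data.

Generative model, per subject ``s`` (random intercept ``u_s ~ N(0,
subject_sd)`` shared across all three predictors) and event with
standardized surprisal ``z``:

* log RT (ms)     ``~ Normal(a0 + u_s + a1 z + a2 z^2, sigma_rt)``
* look-away       ``~ Bernoulli(logistic(b0 + u_s + b1 z + b2 z^2))``,
  with the trial censored after the first success
* predictive look ``~ Bernoulli(logistic(c0 + u_s + c1 z))``, drawn only on
  first appearances after event 0

Default coefficients give the U-shaped (Goldilocks) regime: fastest
reactions and fewest look-aways at intermediate surprisal, and predictive
looks that become rarer as surprisal grows.

``z`` is standardized over the stimulus set's full event pool, the same
pooled convention the analysis uses.

Rendering conventions (all configurable constants below): gaze rests at the
screen-center fixation point with small jitter; a drawn RT becomes an AOI
entry at onset + RT followed by a 300 ms dwell; a drawn predictive look
parks gaze on the box for the last 100 ms before onset (so measured RT is
0, and the truth table records 0); a drawn look-away becomes an 800 ms
off-screen excursion starting 100 ms into the event. Latencies of 1200 ms
or more are recorded as "never fixated" so every programmed behaviour fits
inside its 1500 ms event window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gaze import GazeTrial
from .ideal_observer import SurprisalTrace, score_sequence_set
from .sequences import SequenceSet, SequenceSpec, generate_sequence_set

__all__ = [
    "AgentParams",
    "SimulatedDataset",
    "simulate_event_outcomes",
    "render_gaze_streams",
    "make_benchmark_dataset",
]

TAIL_MS = 100  # pre-onset AOI dwell for predictive looks
DWELL_MS = 300  # post-entry AOI dwell
RT_MAX_MS = 1200  # drawn latencies beyond this count as "never fixated"
LOOKAWAY_START_MS = 100  # excursion offset within the look-away event
LOOKAWAY_RUN_MS = 800  # excursion length (> 750 ms threshold)
FILLER_JITTER_PX = 3.0


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class AgentParams:
    """Ground-truth generative coefficients (U-shaped attention defaults)."""

    rt: tuple[float, float, float] = (5.5, -0.05, 0.04)
    sigma_rt: float = 0.25
    lookaway: tuple[float, float, float] = (-2.2, -0.6, 0.35)
    predictive: tuple[float, float] = (-1.0, -0.5)
    subject_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.sigma_rt <= 0:
            raise ValueError("sigma_rt must be > 0")
        if self.subject_sd < 0:
            raise ValueError("subject_sd must be >= 0")


@dataclass
class SimulatedDataset:
    sequences: SequenceSet
    traces: list[SurprisalTrace]
    truth: pd.DataFrame
    trials: list[GazeTrial]
    params: AgentParams
    seed: int


def _first_appearance_mask(object_ids: np.ndarray) -> np.ndarray:
    seen: set[int] = set()
    mask = np.zeros(len(object_ids), dtype=bool)
    for i, obj in enumerate(object_ids):
        if obj not in seen:
            seen.add(obj)
            mask[i] = True
    return mask


def standardized_surprisal(traces: list[SurprisalTrace], model: str = "unigram") -> dict[str, np.ndarray]:
    """Pooled z-scores of the chosen model's surprisal over the full event pool."""
    if model not in ("unigram", "transitional"):
        raise ValueError("model must be 'unigram' or 'transitional'")
    pool = np.concatenate([getattr(tr, model) for tr in traces])
    mu, sd = pool.mean(), pool.std()
    if sd == 0:
        raise ValueError("surprisal has zero variance across the event pool")
    return {tr.sequence_id: (getattr(tr, model) - mu) / sd for tr in traces}


def simulate_event_outcomes(
    traces: list[SurprisalTrace],
    params: AgentParams,
    n_subjects: int = 5,
    model: str = "unigram",
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Draw per-event outcomes for every subject x sequence.

    Each subject sees every sequence once, in an independently randomized
    order (``trial_number`` is the 1-based position in that order). Events
    after a drawn look-away carry no outcomes (``included=False``).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if not traces:
        raise ValueError("traces must be non-empty")
    rng = np.random.default_rng(rng)
    z_by_seq = standardized_surprisal(traces, model=model)
    a0, a1, a2 = params.rt
    b0, b1, b2 = params.lookaway
    c0, c1 = params.predictive
    u = rng.normal(0.0, params.subject_sd, size=n_subjects)
    rows = []
    for s in range(n_subjects):
        subject_id = f"S{s + 1}"
        order = rng.permutation(len(traces))
        for pos, ti in enumerate(order):
            tr = traces[ti]
            z = z_by_seq[tr.sequence_id]
            n_ev = len(z)
            first = _first_appearance_mask(tr.object_ids)
            eta_rt = a0 + u[s] + a1 * z + a2 * z**2
            p_la = _logistic(b0 + u[s] + b1 * z + b2 * z**2)
            p_pred = _logistic(c0 + u[s] + c1 * z)
            rt_draw = np.exp(rng.normal(eta_rt, params.sigma_rt))
            la_draw = rng.random(n_ev) < p_la
            pred_draw = rng.random(n_ev) < p_pred
            la_hits = np.flatnonzero(la_draw)
            la_event = int(la_hits[0]) if la_hits.size else None
            for e in range(n_ev):
                included = la_event is None or e <= la_event
                pred_defined = included and first[e] and e > 0
                pred = bool(pred_draw[e]) if pred_defined else None
                if not included or e == la_event:
                    rt = None
                elif pred:
                    rt = 0.0
                else:
                    r = float(np.round(rt_draw[e]))
                    rt = r if r < RT_MAX_MS else None
                rows.append(
                    {
                        "subject_id": subject_id,
                        "trial_id": f"{subject_id}_t{pos + 1:03d}",
                        "trial_number": pos + 1,
                        "sequence_id": tr.sequence_id,
                        "event_index": e,
                        "object_id": int(tr.object_ids[e]),
                        "z": z[e],
                        "p_lookaway": p_la[e],
                        "p_predictive": p_pred[e] if pred_defined else np.nan,
                        "rt_ms": rt,
                        "predictive_look": pred,
                        "look_away": bool(la_event is not None and e == la_event),
                        "included": included,
                    }
                )
    df = pd.DataFrame(rows)
    df["rt_ms"] = df["rt_ms"].astype("Float64")
    df["predictive_look"] = df["predictive_look"].astype("boolean")
    return df


def render_gaze_streams(
    truth: pd.DataFrame,
    sequences: SequenceSet | dict[str, SequenceSpec],
    rng: np.random.Generator | int | None = None,
    screen_bounds: tuple[float, float, float, float] | None = None,
) -> list[GazeTrial]:
    """Render 1000 Hz gaze streams realizing the drawn outcomes exactly."""
    rng = np.random.default_rng(rng)
    seq_by_id = sequences.by_id() if isinstance(sequences, SequenceSet) else dict(sequences)
    trials: list[GazeTrial] = []
    for (sub, tid), g in truth.groupby(["subject_id", "trial_id"], sort=False):
        g = g.sort_values("event_index")
        seq = seq_by_id[str(g["sequence_id"].iloc[0])]
        geom = seq.geometry
        if screen_bounds is None:
            bounds = (0.0, 0.0, float(geom.screen[0]), float(geom.screen[1]))
        else:
            bounds = screen_bounds
        total = seq.duration_ms
        fx, fy = geom.filler_point
        x = fx + rng.normal(0.0, FILLER_JITTER_PX, size=total)
        y = fy + rng.normal(0.0, FILLER_JITTER_PX, size=total)
        valid = np.ones(total, dtype=bool)
        for row in g.itertuples(index=False):
            ev = seq.events[row.event_index]
            cx, cy = seq.event_center(ev)
            onset, dur = ev.onset_ms, ev.duration_ms
            pred = row.predictive_look
            if pred is not pd.NA and pred is not None and bool(pred):
                x[onset - TAIL_MS : onset] = cx
                y[onset - TAIL_MS : onset] = cy
            if pd.notna(row.rt_ms):
                rt = int(row.rt_ms)
                if rt >= dur:
                    raise ValueError("drawn RT exceeds the event duration")
                entry = onset + rt
                end = min(entry + DWELL_MS, onset + dur - TAIL_MS)
                x[entry:end] = cx
                y[entry:end] = cy
            if row.look_away:
                s0 = onset + LOOKAWAY_START_MS
                x[s0 : s0 + LOOKAWAY_RUN_MS] = bounds[0] - 500.0
                y[s0 : s0 + LOOKAWAY_RUN_MS] = bounds[1] - 500.0
        trials.append(
            GazeTrial(
                subject_id=str(sub),
                trial_id=str(tid),
                trial_number=int(g["trial_number"].iloc[0]),
                sequence_id=seq.sequence_id,
                t_ms=np.arange(total),
                x_px=x,
                y_px=y,
                valid=valid,
                screen_bounds=bounds,
                aoi_radius_px=geom.aoi_radius_px,
            )
        )
    return trials


def make_benchmark_dataset(
    n_subjects: int = 5,
    n_sequences: int = 80,
    length: int = 30,
    params: AgentParams | None = None,
    seed: int = 0,
    model: str = "unigram",
    candidate_pool_size: int = 400,
    alpha: float = 1.0,
    render: bool = True,
) -> SimulatedDataset:
    """Full benchmark at the study's scale: 5 subjects x 80 sequences x 30 events."""
    params = params or AgentParams()
    rng = np.random.default_rng(seed)
    seq_seed = int(rng.integers(2**31))
    sset = generate_sequence_set(
        n_sequences=n_sequences,
        length=length,
        candidate_pool_size=candidate_pool_size,
        rng_seed=seq_seed,
        alpha=alpha,
    )
    traces = score_sequence_set(sset, alpha=alpha)
    truth = simulate_event_outcomes(traces, params, n_subjects=n_subjects, model=model, rng=rng)
    trials = render_gaze_streams(truth, sset, rng=rng) if render else []
    return SimulatedDataset(sequences=sset, traces=traces, truth=truth, trials=trials, params=params, seed=seed)
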
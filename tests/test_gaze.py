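"""Gaze-measure extraction on constructed sample streams."""

import numpy as np
import pandas as pd
import pytest

from goldilocks.gaze import (
    GazeTrial,
    build_event_table,
    compute_look_away,
    compute_predictive_look,
    compute_rt,
    in_aoi,
    trial_measures,
)
from goldilocks.ideal_observer import score_sequence_set

from conftest import make_seq


def make_trial(seq, geometry, subject="S1", trial="t1", number=1):
    """Stream resting at the filler point; tests paint behaviour onto it."""
    total = seq.duration_ms
    fx, fy = geometry.filler_point
    return GazeTrial(
        subject_id=subject,
        trial_id=trial,
        trial_number=number,
        sequence_id=seq.sequence_id,
        t_ms=np.arange(total),
        x_px=np.full(total, fx),
        y_px=np.full(total, fy),
        valid=np.ones(total, dtype=bool),
        screen_bounds=(0.0, 0.0, float(geometry.screen[0]), float(geometry.screen[1])),
        aoi_radius_px=geometry.aoi_radius_px,
    )


def put_gaze(trial, t0, t1, xy):
    trial.x_px[t0:t1] = xy[0]
    trial.y_px[t0:t1] = xy[1]


def test_in_aoi_boundary_and_validity():
    assert in_aoi(100.0, 100.0, True, (100.0, 100.0), 50.0)
    assert in_aoi(150.0, 100.0, True, (100.0, 100.0), 50.0)  # boundary inclusive
    assert not in_aoi(151.0, 100.0, True, (100.0, 100.0), 50.0)
    assert not in_aoi(100.0, 100.0, False, (100.0, 100.0), 50.0)  # track loss
    with pytest.raises(ValueError):
        in_aoi(0.0, 0.0, True, (0.0, 0.0), 0.0)


def test_compute_rt_entry_latency(geometry):
    seq = make_seq([0, 1, 2], geometry)
    trial = make_trial(seq, geometry)
    ev = seq.events[1]
    put_gaze(trial, ev.onset_ms + 230, ev.onset_ms + 500, seq.event_center(ev))
    assert compute_rt(trial, seq, ev) == 230.0


def test_compute_rt_zero_when_already_inside(geometry):
    seq = make_seq([0, 1, 2], geometry)
    trial = make_trial(seq, geometry)
    ev = seq.events[0]
    put_gaze(trial, 0, 100, seq.event_center(ev))
    assert compute_rt(trial, seq, ev) == 0.0


def test_compute_rt_absent_when_never_in_aoi(geometry):
    seq = make_seq([0, 1, 2], geometry)
    trial = make_trial(seq, geometry)
    assert compute_rt(trial, seq, seq.events[2]) is None


def test_predictive_look_true_on_first_appearance(geometry):
    seq = make_seq([0, 1, 2], geometry)
    trial = make_trial(seq, geometry)
    ev = seq.events[1]  # first appearance of object 1
    put_gaze(trial, ev.onset_ms - 50, ev.onset_ms, seq.event_center(ev))
    assert compute_predictive_look(trial, seq, ev) is True


def test_predictive_look_false_when_gaze_elsewhere(geometry):
    seq = make_seq([0, 1, 2], geometry)
    trial = make_trial(seq, geometry)
    assert compute_predictive_look(trial, seq, seq.events[1]) is False
    # off-screen gaze in the pre-onset window is also False
    trial.x_px[seq.events[2].onset_ms - 1] = -100.0
    assert compute_predictive_look(trial, seq, seq.events[2]) is False


def test_predictive_look_absent_on_repeats_and_event_zero(geometry):
    seq = make_seq([0, 1, 1, 0], geometry)
    trial = make_trial(seq, geometry)
    assert compute_predictive_look(trial, seq, seq.events[0]) is None  # no pre-onset sample
    assert compute_predictive_look(trial, seq, seq.events[2]) is None  # repeat of object 1
    assert compute_predictive_look(trial, seq, seq.events[3]) is None  # repeat of object 0


def test_look_away_event_index(geometry):
    seq = make_seq([0, 1, 2, 0, 1, 2, 0, 1], geometry)
    trial = make_trial(seq, geometry)
    onset5 = seq.events[5].onset_ms
    put_gaze(trial, onset5 + 100, onset5 + 900, (-500.0, -500.0))  # 800 ms off-screen
    assert compute_look_away(trial, seq) == 5


def test_look_away_requires_threshold_run(geometry):
    seq = make_seq([0, 1, 2, 0], geometry)
    trial = make_trial(seq, geometry)
    put_gaze(trial, 1000, 1600, (-500.0, -500.0))  # 600 ms < 750 ms
    assert compute_look_away(trial, seq) is None


def test_look_away_first_run_wins(geometry):
    seq = make_seq([0, 1, 2, 0, 1, 2, 0, 1], geometry)
    trial = make_trial(seq, geometry)
    for ev_idx in (3, 7):
        onset = seq.events[ev_idx].onset_ms
        put_gaze(trial, onset + 50, onset + 850, (-500.0, -500.0))
    assert compute_look_away(trial, seq) == 3


def test_track_loss_counts_as_offscreen(geometry):
    seq = make_seq([0, 1], geometry)
    trial = make_trial(seq, geometry)
    trial.valid[200:1000] = False  # 800 ms track loss
    assert compute_look_away(trial, seq) == 0


def test_trial_measures_censors_after_look_away(geometry):
    seq = make_seq([0, 1, 2, 0, 1, 2], geometry)
    trial = make_trial(seq, geometry)
    onset2 = seq.events[2].onset_ms
    put_gaze(trial, onset2 + 10, onset2 + 810, (-500.0, -500.0))
    df = trial_measures(trial, seq)
    assert bool(df.loc[df.event_index == 2, "look_away"].item())
    assert df.loc[df.event_index > 2, "included"].eq(False).all()
    assert df.loc[df.event_index > 2, "rt_ms"].isna().all()
    assert df.loc[df.event_index > 2, "predictive_look"].isna().all()
    # covariates: event 0 has no distance; repeats flagged against previous event
    assert df.loc[df.event_index == 0, "distance_px"].isna().item()
    assert not df["is_repeat"].iloc[0]


def test_event_table_cardinality_join_and_idempotence(small_dataset):
    ds = small_dataset
    seqs = ds.sequences.by_id()
    t1 = build_event_table(ds.trials, seqs, ds.traces)
    assert len(t1) == 3 * 20 * 15  # subjects x sequences x events
    # join integrity: surprisal columns equal the traces bit-for-bit
    by_id = {tr.sequence_id: tr for tr in ds.traces}
    for (sid, _), g in t1.groupby(["sequence_id", "trial_id"]):
        tr = by_id[sid]
        np.testing.assert_array_equal(
            g.sort_values("event_index")["unigram_surprisal_bits"].to_numpy(), tr.unigram
        )
        np.testing.assert_array_equal(
            g.sort_values("event_index")["transitional_surprisal_bits"].to_numpy(), tr.transitional
        )
    t2 = build_event_table(ds.trials, seqs, ds.traces)
    pd.testing.assert_frame_equal(t1, t2)


def test_event_table_requires_traces(small_dataset):
    ds = small_dataset
    with pytest.raises(ValueError, match="seq0"):
        build_event_table(ds.trials, ds.sequences.by_id(), ds.traces[5:])


def test_aoi_exclusivity(small_dataset):
    """With enforced box separation, no sample can sit inside two AOIs."""
    for seq in small_dataset.sequences.sequences[:5]:
        c = np.asarray(seq.geometry.box_centers)
        d = np.linalg.norm(c[:, None] - c[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 2 * seq.geometry.aoi_radius_px
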
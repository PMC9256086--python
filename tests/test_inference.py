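"""Standardization, mixed-model recovery, GAM smooths, and invariances."""

import numpy as np
import pandas as pd
import pytest

from goldilocks.inference import (
    GamFit,
    RegressionSpec,
    fit_gam,
    fit_mixed_linear,
    fit_mixed_logistic,
    results_to_frame,
    run_analysis,
    standardize_surprisal,
)
from goldilocks.ideal_observer import traces_to_frame
from goldilocks.simulate import AgentParams, simulate_event_outcomes


def truth_event_table(ds_or_traces, params=None, n_subjects=5, rng=0):
    """Analysis-ready table straight from drawn outcomes (no gaze rendering)."""
    traces = ds_or_traces
    truth = simulate_event_outcomes(traces, params or AgentParams(), n_subjects=n_subjects, rng=rng)
    surp = traces_to_frame(traces)[
        ["sequence_id", "event_index", "unigram_surprisal_bits", "transitional_surprisal_bits"]
    ]
    tab = truth.drop(columns=["z"]).merge(surp, on=["sequence_id", "event_index"])
    tab["is_repeat"] = tab.groupby("trial_id")["object_id"].shift(1).eq(tab["object_id"]).fillna(False)
    dist = np.random.default_rng(99).uniform(300.0, 900.0, len(tab))
    tab["distance_px"] = pd.array(np.where(tab["event_index"] > 0, dist, np.nan), dtype="Float64")
    return tab


def test_standardize_surprisal_definition(small_event_table):
    tab = standardize_surprisal(small_event_table, "unigram")
    inc = tab[tab["included"]]
    assert inc["z"].mean() == pytest.approx(0.0, abs=1e-10)
    assert inc["z"].std(ddof=0) == pytest.approx(1.0, abs=1e-10)
    np.testing.assert_allclose(tab["z2"], tab["z"] ** 2)


def test_standardize_rejects_constant_surprisal(small_event_table):
    bad = small_event_table.copy()
    bad["unigram_surprisal_bits"] = 1.0
    with pytest.raises(ValueError, match="variance"):
        standardize_surprisal(bad, "unigram")


def test_standardization_is_log_base_invariant(small_event_table):
    """Rescaling surprisal bits -> nats leaves z (hence all fits) unchanged."""
    nats = small_event_table.copy()
    nats["unigram_surprisal_bits"] *= np.log(2)
    z_bits = standardize_surprisal(small_event_table, "unigram")["z"]
    z_nats = standardize_surprisal(nats, "unigram")["z"]
    np.testing.assert_allclose(z_bits, z_nats, atol=1e-8)


@pytest.fixture(scope="module")
def bench_table(small_dataset):
    tab = truth_event_table(small_dataset.traces, n_subjects=5, rng=31)
    return standardize_surprisal(tab, "unigram", scope="all")


def test_linear_mixed_model_recovers_rt_coefficients(bench_table):
    res = fit_mixed_linear(bench_table, RegressionSpec("rt"))
    assert res.converged
    truth = {"intercept": 5.5, "z": -0.05, "z2": 0.04}
    for term, val in truth.items():
        c = res.coef(term)
        assert abs(c["estimate"] - val) < 3 * c["se"], term
    assert res.random_intercept_variance > 0


def test_logistic_mixed_model_recovers_lookaway_coefficients(bench_table):
    res = fit_mixed_logistic(bench_table, RegressionSpec("lookaway"))
    assert res.converged and res.method == "AGQ-ML"
    truth = {"intercept": -2.2, "z": -0.6, "z2": 0.35}
    for term, val in truth.items():
        c = res.coef(term)
        assert abs(c["estimate"] - val) < 3 * c["se"], term
        assert np.sign(c["estimate"]) == np.sign(val), term


def test_logistic_model_recovers_predictive_coefficient(bench_table):
    res = fit_mixed_logistic(bench_table, RegressionSpec("predictive"))
    assert "z2" not in set(res.coefficients["term"])  # linear term only
    c = res.coef("z")
    assert c["estimate"] < 0
    assert abs(c["estimate"] - (-0.5)) < 3 * c["se"]


def test_degenerate_outcome_is_flagged(bench_table):
    tab = bench_table.copy()
    tab["look_away"] = False
    res = fit_mixed_logistic(tab, RegressionSpec("lookaway"))
    assert not res.converged
    assert res.method == "degenerate"
    assert res.coefficients["estimate"].isna().all()


def test_controlled_fits_include_covariates(bench_table):
    res = fit_mixed_linear(bench_table, RegressionSpec("rt", controlled=True))
    assert set(res.coefficients["term"]) == {"intercept", "z", "z2", "is_repeat", "distance_z", "trial_z"}


def test_fit_is_log_base_invariant(bench_table, small_dataset):
    tab = truth_event_table(small_dataset.traces, n_subjects=5, rng=31)
    nats = tab.copy()
    nats["unigram_surprisal_bits"] *= np.log(2)
    a = fit_mixed_linear(standardize_surprisal(tab, "unigram", scope="all"), RegressionSpec("rt"))
    b = fit_mixed_linear(standardize_surprisal(nats, "unigram", scope="all"), RegressionSpec("rt"))
    np.testing.assert_allclose(a.coefficients["estimate"], b.coefficients["estimate"], atol=1e-8)
    np.testing.assert_allclose(a.coefficients["p"], b.coefficients["p"], atol=1e-8)


def _quadratic_table(noise_sd, n=3000, seed=0):
    """Synthetic event table with log RT an exact quadratic in surprisal."""
    rng = np.random.default_rng(seed)
    s = rng.uniform(0.5, 4.5, n)
    y = 0.3 * (s - 2.5) ** 2 + 5.0 + rng.normal(0, noise_sd, n)
    return pd.DataFrame(
        {
            "subject_id": np.repeat([f"S{i}" for i in range(5)], n // 5),
            "trial_id": "t",
            "trial_number": 1,
            "sequence_id": "q",
            "event_index": np.arange(n),
            "rt_ms": pd.array(np.exp(y), dtype="Float64"),
            "predictive_look": pd.array([None] * n, dtype="boolean"),
            "look_away": False,
            "included": True,
            "is_repeat": False,
            "distance_px": pd.array([400.0] * n, dtype="Float64"),
            "unigram_surprisal_bits": s,
            "transitional_surprisal_bits": s,
        }
    )


def test_gam_recovers_noiseless_quadratic():
    tab = standardize_surprisal(_quadratic_table(noise_sd=1e-6), "unigram")
    gf = fit_gam(tab, RegressionSpec("rt"))
    s = gf.grid
    inner = (s > np.quantile(s, 0.05)) & (s < np.quantile(s, 0.95))
    target = 0.3 * (s - 2.5) ** 2 + 5.0
    assert np.max(np.abs(gf.mean[inner] - target[inner])) < 0.05
    assert gf.interior_minimum() == pytest.approx(2.5, abs=0.3)


def test_gam_flat_for_constant_mean():
    tab = _quadratic_table(noise_sd=0.3)
    tab["rt_ms"] = pd.array(np.exp(5.0 + np.random.default_rng(1).normal(0, 0.3, len(tab))), dtype="Float64")
    tab = standardize_surprisal(tab, "unigram")
    gf = fit_gam(tab, RegressionSpec("rt"))
    assert np.all(gf.ci_lower <= gf.mean.mean() + 0.05)
    assert np.all(gf.ci_upper >= gf.mean.mean() - 0.05)
    assert gf.ci_upper.max() - gf.ci_lower.min() < 0.5  # tight, roughly flat band


def test_gam_requires_enough_rows():
    tab = standardize_surprisal(_quadratic_table(noise_sd=0.1, n=40), "unigram")
    with pytest.raises(ValueError, match="rows"):
        fit_gam(tab, RegressionSpec("rt"))


def test_gam_bins_partition_the_range(bench_table):
    gf = fit_gam(bench_table, RegressionSpec("rt"))
    assert len(gf.bin_centers) == 3
    assert np.all(np.isfinite(gf.bin_means))
    assert np.all((gf.ci_lower <= gf.mean) & (gf.mean <= gf.ci_upper))


def test_run_analysis_bundle(bench_table):
    bundle = run_analysis(bench_table, scope="all", with_gams=False)
    assert len(bundle["fits"]) == 12 and not bundle["errors"]
    # U shape detected in raw unigram fits for rt and look-away
    for outcome in ("rt", "lookaway"):
        res = bundle["fits"][(outcome, "unigram", False)]
        assert res.coef("z")["estimate"] < 0 < res.coef("z2")["estimate"]
        assert res.coef("z2")["p"] < 0.05
    frame = results_to_frame(bundle["fits"])
    assert frame.groupby(["outcome", "model", "controlled"]).ngroups == 12
    # determinism: rerunning yields identical coefficient tables
    again = results_to_frame(run_analysis(bench_table, scope="all", with_gams=False)["fits"])
    pd.testing.assert_frame_equal(frame, again)


def test_run_analysis_rejects_empty_table():
    with pytest.raises(ValueError, match="empty"):
        run_analysis(pd.DataFrame())
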
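"""Tests of bound-event extraction, survival curves, bleach correction and fits."""

import numpy as np
import pandas as pd
import pytest

import tfkinetics as tk
from tfkinetics.residence import SurvivalCurve

from conftest import quantized_control_durations, quantized_event_durations


# ---------------------------------------------------------------------------
# event extraction
# ---------------------------------------------------------------------------

def test_immobile_track_single_event(immobile_track):
    events = tk.extract_bound_events(immobile_track)
    assert len(events) == 1
    assert events.iloc[0]["n_frames"] == 10
    assert events.iloc[0]["duration_s"] == pytest.approx(1.0)


def test_large_jump_splits_run(immobile_track):
    t = pd.concat([
        immobile_track,
        immobile_track.assign(frame=immobile_track["frame"] + 10,
                              x_um=immobile_track["x_um"] + 0.5),
    ]).reset_index(drop=True)
    # two 10-frame immobile halves separated by a 0.5 um jump: both survive
    events = tk.extract_bound_events(t)
    assert len(events) == 2
    # shorten the halves below the temporal threshold: nothing survives
    short = t[t["frame"].isin(list(range(7)) + list(range(10, 17)))]
    assert len(tk.extract_bound_events(short)) == 0


def test_blink_gap_counts_toward_duration():
    frames = list(range(5)) + list(range(8, 13))  # 3-frame closed gap
    t = pd.DataFrame({"track_id": 0, "frame": frames, "x_um": 1.0, "y_um": 1.0})
    events = tk.extract_bound_events(t)
    assert len(events) == 1
    assert events.iloc[0]["n_frames"] == 13


def test_event_recovery_from_simulation():
    """Events >= 1 s in the ground-truth table are recovered from noisy tracks."""
    cfg = tk.SmtSimConfig(
        n_molecules=3000, frac_bound=1.0, frac_slow=0.0, frac_free=0.0,
        t_fast=2.0, t_slow=2.0, frac_slow_bound=0.0, sigma_loc=0.03,
        p_bleach=0.0, p_blink=0.0, n_frames=120, seed=21,
    )
    locs, truth = tk.simulate_tracks(cfg)
    tracks = locs.rename(columns={"track_truth_id": "track_id"})
    events = tk.extract_bound_events(tracks)
    truth_frames = np.minimum(np.ceil(truth["t_true_s"] / 0.1), cfg.n_frames)
    expected = truth_frames[truth_frames >= 10]
    got = events.set_index("track_id")["n_frames"]
    matched = expected.index.intersection(got.index)
    assert len(matched) / len(expected) >= 0.9
    err = np.abs(got.loc[matched] - expected.loc[matched])
    assert (err <= 1).mean() >= 0.9


# ---------------------------------------------------------------------------
# survival curves and photobleaching correction
# ---------------------------------------------------------------------------

def test_survival_curve_direct_counts():
    s = tk.survival_curve(np.array([1.0, 1.0, 2.0, 4.0]))
    assert np.allclose(s.times, [1.0, 2.0, 4.0])
    assert np.allclose(s.survival, [1.0, 0.5, 0.25])
    assert s.n_events == 4


def test_survival_curve_degenerate_and_empty():
    s = tk.survival_curve(np.array([2.0, 2.0, 2.0]))
    assert s.times.size == 1 and s.survival[0] == 1.0
    with pytest.raises(ValueError):
        tk.survival_curve(np.array([]))


def test_survival_log_slope_recovers_rate():
    rng = np.random.default_rng(22)
    s = tk.survival_curve(rng.exponential(2.0, size=10_000))
    mask = s.survival > 0.02
    slope = np.polyfit(s.times[mask], np.log(s.survival[mask]), 1)[0]
    assert -slope == pytest.approx(0.5, rel=0.05)


def test_correction_identities():
    t = np.arange(1, 30) * 0.1
    target = SurvivalCurve(times=t, survival=np.exp(-t / 0.7), n_events=100)
    self_corr = tk.correct_photobleaching(target, target)
    assert np.allclose(self_corr.survival, 1.0)
    flat = SurvivalCurve(times=np.array([0.05, 10.0]),
                         survival=np.array([1.0, 1.0]), n_events=100)
    ident = tk.correct_photobleaching(target, flat)
    assert np.allclose(ident.survival, target.survival / target.survival[0])


def test_correction_closed_form_product():
    """Dividing exp(-t/tau) exp(-k t) by exp(-k t) returns exp(-t/tau) exactly."""
    tau, k_bl = 4.0, 0.2
    t = np.arange(1, 200) * 0.1
    target = SurvivalCurve(times=t, survival=np.exp(-t / tau) * np.exp(-k_bl * t),
                           n_events=1000)
    control = SurvivalCurve(times=t, survival=np.exp(-k_bl * t), n_events=1000)
    corr = tk.correct_photobleaching(target, control)
    expected = np.exp(-corr.times / tau) / np.exp(-corr.times[0] / tau)
    assert np.allclose(corr.survival, expected, atol=1e-9)
    # floor: control drops below 0.05 at t = -ln(0.05)/0.2 ~ 15 s
    assert corr.times[-1] <= -np.log(0.05) / k_bl + 0.1


def test_correction_truncates_with_warning():
    t = np.arange(1, 50) * 0.1
    target = SurvivalCurve(times=t, survival=np.exp(-t), n_events=10)
    control = SurvivalCurve(times=t[:20], survival=np.exp(-0.1 * t[:20]), n_events=10)
    with pytest.warns(UserWarning, match="truncated"):
        corr = tk.correct_photobleaching(target, control)
    assert corr.times[-1] <= control.times[-1]


# ---------------------------------------------------------------------------
# exponential fitting and model selection
# ---------------------------------------------------------------------------

def test_fit_noiseless_single_exponential():
    t = np.arange(1, 100) * 0.1
    curve = SurvivalCurve(times=t, survival=np.exp(-t / 2.0) / np.exp(-t[0] / 2.0),
                          n_events=500)
    fit = tk.fit_exponential_survival(curve, 1)
    assert fit.lifetimes[0] == pytest.approx(2.0, rel=1e-6)
    assert fit.fractions[0] == pytest.approx(1.0)
    assert fit.rss < 1e-12


def test_fit_noiseless_two_component_mixture():
    """The wild-type-like mixture 0.957 e^-t/0.53 + 0.043 e^-t/4.13 on a
    100 ms grid is recovered to better than 1%."""
    t = np.arange(1, 301) * 0.1
    y = 0.957 * np.exp(-t / 0.53) + 0.043 * np.exp(-t / 4.13)
    curve = SurvivalCurve(times=t, survival=y / y[0], n_events=10_000)
    fit = tk.fit_exponential_survival(curve, 2)
    assert fit.lifetimes[0] == pytest.approx(0.53, rel=0.01)
    assert fit.lifetimes[1] == pytest.approx(4.13, rel=0.01)
    assert fit.fractions[1] == pytest.approx(0.043, abs=0.002)


def test_fit_matches_grid_search_oracle():
    """Brute-force grid search over (A, tau) finds the same mono-exponential
    optimum within grid resolution."""
    rng = np.random.default_rng(23)
    t = np.arange(1, 60) * 0.1
    y = np.exp(-t / 1.7) + rng.normal(0, 0.01, size=t.size)
    y = np.minimum.accumulate(np.clip(y, 1e-6, None))
    curve = SurvivalCurve(times=t, survival=y / y[0], n_events=100)
    fit = tk.fit_exponential_survival(curve, 1)

    amps = np.linspace(0.5, 1.5, 201)
    taus = np.geomspace(0.5, 5.0, 401)
    grid_rss = np.inf
    grid_best = None
    for a in amps:
        model = a * np.exp(-t[None, :] / taus[:, None])
        rss = ((model - curve.survival[None, :]) ** 2).sum(axis=1)
        i = int(np.argmin(rss))
        if rss[i] < grid_rss:
            grid_rss = rss[i]
            grid_best = (a, taus[i])
    assert fit.rss <= grid_rss + 1e-12
    assert fit.lifetimes[0] == pytest.approx(grid_best[1], rel=0.01)


def test_fit_scale_equivariance():
    rng = np.random.default_rng(24)
    durations = quantized_event_durations(rng, 20_000, 0.5, 4.0, 0.3, p_bleach=0.0)
    c = 3.7
    fit = tk.fit_exponential_survival(tk.survival_curve(durations), 2)
    fit_scaled = tk.fit_exponential_survival(tk.survival_curve(durations * c), 2)
    assert np.allclose(fit_scaled.lifetimes, c * fit.lifetimes, rtol=1e-4)
    assert np.allclose(fit_scaled.fractions, fit.fractions, atol=1e-4)


def test_ftest_equal_rss_prefers_simple():
    f1 = tk.ExpFitResult(1, np.array([1.0]), np.array([2.0]), 0.5, 100, 2, np.array([0.1]))
    f2 = tk.ExpFitResult(2, np.array([0.5, 0.5]), np.array([1.0, 3.0]), 0.5, 100, 4,
                         np.array([0.1, 0.1]))
    res = tk.compare_models_ftest(f1, f2)
    assert res.F == 0.0
    assert res.p_value == 1.0
    assert res.preferred == 1


def test_ftest_power_on_two_component_truth():
    """With 1e4 events from a wild-type-like mixture the bi-exponential model
    is always selected."""
    for seed in range(5):
        rng = np.random.default_rng(100 + seed)
        durations = quantized_event_durations(rng, 60_000, 0.53, 4.13, 0.043)
        curve = tk.survival_curve(durations)
        assert curve.n_events >= 8_000
        model = tk.ExponentialSurvivalModel(curve)
        res = tk.compare_models_ftest(model.fit(1), model.fit(2))
        assert res.preferred == 2


def test_mle_flag_agrees_on_clean_mixture():
    """The likelihood-based alternative recovers an unquantized mixture."""
    rng = np.random.default_rng(25)
    slow = rng.random(30_000) < 0.2
    durations = rng.exponential(np.where(slow, 4.0, 0.5))
    curve = tk.survival_curve(durations)
    mle = tk.fit_exponential_survival(curve, 2, method="mle")
    assert mle.lifetimes[0] == pytest.approx(0.5, rel=0.1)
    assert mle.lifetimes[1] == pytest.approx(4.0, rel=0.1)


# ---------------------------------------------------------------------------
# composed pipeline
# ---------------------------------------------------------------------------

def test_parameter_recovery_over_replicates():
    """Across seeded replicates of the wild-type condition the median relative
    error of the slow lifetime stays below 15% and of its fraction below 30%."""
    t_slow_err, frac_err = [], []
    for seed in range(50):
        rng = np.random.default_rng(1000 + seed)
        target = quantized_event_durations(rng, 14_000, 0.53, 4.13, 0.043)
        control = quantized_control_durations(rng, 6_000)
        corrected = tk.correct_photobleaching(
            tk.survival_curve(target), tk.survival_curve(control)
        )
        fit = tk.fit_exponential_survival(corrected, 2)
        t_slow_err.append(abs(fit.lifetimes[1] - 4.13) / 4.13)
        frac_err.append(abs(fit.fractions[1] - 0.043) / 0.043)
    assert np.median(t_slow_err) <= 0.15
    assert np.median(frac_err) <= 0.30


def test_control_survival_reflects_bleach_rate(immobile_control_tracks):
    """The uncorrected immobile-control survival decays with the
    photobleaching lifetime 1/k_bl."""
    events = tk.extract_bound_events(immobile_control_tracks)
    fit = tk.fit_exponential_survival(tk.survival_curve(events), 1)
    p_bleach, dt = 0.01, 0.1
    k_bl = -np.log(1 - p_bleach) / dt
    assert fit.lifetimes[0] == pytest.approx(1 / k_bl, rel=0.1)


def test_control_as_target_prefers_mono(immobile_control_tracks):
    """When the target is the immobile control itself, the corrected curve is
    flat (self-division) and the mono-exponential model wins."""
    summary = tk.estimate_binding_times(
        immobile_control_tracks, immobile_control_tracks
    )
    assert summary.preferred_model == 1
    # flat curve: fitted lifetime far exceeds the bleaching lifetime 1/k_bl ~ 10 s
    assert summary.t_slow > 3 * 10.0


def test_estimate_binding_times_recovers_mixture(immobile_control_tracks):
    cfg = tk.SmtSimConfig(
        n_molecules=12_000, frac_bound=1.0, frac_slow=0.0, frac_free=0.0,
        t_fast=0.53, t_slow=4.13, frac_slow_bound=0.043, seed=78,
    )
    locs, _ = tk.simulate_tracks(cfg)
    from tfkinetics.pipeline import tracks_from_truth

    summary = tk.estimate_binding_times(tracks_from_truth(locs), immobile_control_tracks)
    assert summary.preferred_model == 2
    assert summary.t_slow == pytest.approx(4.13, rel=0.2)
    assert summary.t_fast == pytest.approx(0.53, rel=0.1)
    assert "t_slow" in summary.summary() or "t_slow = " in summary.summary()
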
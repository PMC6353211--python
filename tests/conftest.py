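"""Shared fixtures: small simulated data sets reused across test modules."""

import numpy as np
import pandas as pd
import pytest

import tfkinetics as tk
from tfkinetics.pipeline import tracks_from_truth


@pytest.fixture(scope="session")
def immobile_control_tracks():
    """Immobile-control movie: no unbinding, tracks end by photobleaching only."""
    cfg = tk.SmtSimConfig(
        n_molecules=6000, frac_bound=1.0, frac_slow=0.0, frac_free=0.0,
        t_fast=np.inf, t_slow=np.inf, frac_slow_bound=0.0, seed=4242,
    )
    locs, _ = tk.simulate_tracks(cfg)
    return tracks_from_truth(locs)


@pytest.fixture()
def immobile_track():
    """A single noiseless immobile track of 10 frames at the origin-ish."""
    return pd.DataFrame({
        "track_id": 0,
        "frame": np.arange(10),
        "x_um": 5.0,
        "y_um": 5.0,
    })


def quantized_event_durations(
    rng, n_events, t_fast, t_slow, frac_slow, cycle_dt=0.1, p_bleach=0.01,
    min_frames=10, max_frames=400,
):
    """Event-level forward model of observed bound durations.

    Dwells are a two-exponential mixture; the camera reports
    ceil(dwell / cycle_dt) frames, truncated by a geometric photobleaching
    time, the movie end, and the minimum-length filter. Returns durations in
    seconds (n_frames * cycle_dt convention).
    """
    slow = rng.random(n_events) < frac_slow
    dwell = rng.exponential(np.where(slow, t_slow, t_fast))
    frames = np.ceil(dwell / cycle_dt).astype(int)
    if p_bleach > 0:
        bleach = rng.geometric(p_bleach, size=n_events)
        frames = np.minimum(frames, bleach)
    frames = np.minimum(frames, max_frames)
    frames = frames[frames >= min_frames]
    return frames * cycle_dt


def quantized_control_durations(rng, n_events, cycle_dt=0.1, p_bleach=0.01,
                                min_frames=10, max_frames=400):
    """Photobleaching-only observed durations for the immobile control."""
    frames = np.minimum(rng.geometric(p_bleach, size=n_events), max_frames)
    frames = frames[frames >= min_frames]
    return frames * cycle_dt
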
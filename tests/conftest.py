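"""Shared fixtures: small synthetic track sets built at test time."""

import numpy as np
import pandas as pd
import pytest

from sptmap import simkit

DT = 0.035  # frame interval used throughout, seconds


def make_track(positions, track_id=0, channel="ch0", frames=None):
    """Trajectory table from an (n, 2) array of μm positions."""
    positions = np.asarray(positions, dtype=float)
    if frames is None:
        frames = np.arange(len(positions))
    return pd.DataFrame(
        {
            "track_id": track_id,
            "frame": np.asarray(frames, dtype=np.int64),
            "x_um": positions[:, 0],
            "y_um": positions[:, 1],
            "channel": channel,
        }
    )


@pytest.fixture(scope="session")
def brownian_tracks():
    """1000 noiseless Brownian tracks (D = 0.19 μm²/s, 101 frames)."""
    cfg = simkit.SimConfig(rng_seed=42, localization_sd=0.0, n_frames=101)
    tracks, gt = simkit.simulate_tracks(
        cfg, simkit.MotionSpec(kind="brownian", D=0.19), 1000, track_length=101
    )
    return tracks, gt


@pytest.fixture(scope="session")
def two_state_tracks():
    """Two-state switching tracks in the 0.5 s / 1.3 s lifetime regime."""
    cfg = simkit.SimConfig(rng_seed=7, localization_sd=0.0, n_frames=101)
    spec = simkit.MotionSpec(
        kind="two_state", D1=0.4, D2=0.1, k12=2.0, k21=1.0 / 1.3
    )
    tracks, gt = simkit.simulate_tracks(cfg, spec, 200, track_length=101)
    return tracks, gt, spec
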
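"""Co-movement detection and the area-normalized colocalization null."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sptmap import comovement, simkit
from tests.conftest import DT, make_track


def track_at(frames, xy, track_id=0, channel="c"):
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    if len(xy) == 1:
        xy = np.repeat(xy, len(frames), axis=0)
    return make_track(xy, track_id=track_id, channel=channel, frames=frames)


class TestFrameDistances:
    def test_identical_positions_give_single_zero(self):
        m = track_at([0], [1.0, 1.0])
        r = track_at([0], [1.0, 1.0], track_id=5)
        d = comovement.frame_distances(m, r)
        assert len(d) == 1 and d.distance_um.iloc[0] == 0.0

    def test_cross_product_counting(self):
        m = pd.concat([track_at([0], [i, 0], track_id=i) for i in range(2)])
        r = pd.concat([track_at([0], [i, 5], track_id=i) for i in range(3)])
        assert len(comovement.frame_distances(m, r)) == 6

    def test_disjoint_frames_give_empty(self):
        m = track_at([0, 1], [0.0, 0.0])
        r = track_at([5, 6], [0.0, 0.0])
        assert comovement.frame_distances(m, r).empty


class TestNormalizedDistribution:
    def test_independent_channels_are_flat(self):
        rng = np.random.default_rng(0)
        n_frames, per_frame, field = 30, 20, 30.0

        def uniform_channel(channel):
            return pd.DataFrame({
                "track_id": np.arange(n_frames * per_frame),
                "frame": np.repeat(np.arange(n_frames), per_frame),
                "x_um": rng.uniform(2, field - 2, n_frames * per_frame),
                "y_um": rng.uniform(2, field - 2, n_frames * per_frame),
                "channel": channel,
            })

        dists = comovement.frame_distances(
            uniform_channel("m"), uniform_channel("r")
        )
        dd = comovement.normalized_distance_distribution(dists, 0.107, 2.0)
        assert dists.shape[0] >= 10_000
        med = np.median(dd.density)
        annulus = np.pi * (dd.bin_edges[1:] ** 2 - dd.bin_edges[:-1] ** 2)
        sd = np.sqrt(np.maximum(med * annulus, 1.0)) / annulus  # Poisson sd of density
        assert np.all(np.abs(dd.density - med) < 4 * sd)
        _, p = comovement.flatness_test(dd)
        assert p > 0.01

    def test_comoving_population_peaks_below_three_pixels(self):
        cfg = simkit.SimConfig(rng_seed=1, field_size=(30, 30),
                               localization_sd=0.01, mean_track_length=10)
        mc = simkit.MotionSpec(kind="two_state", D1=0.4, D2=0.1, k12=2.0, k21=0.77)
        mf = simkit.MotionSpec(kind="brownian", D=0.4)
        mrna, ribo, _ = simkit.simulate_comoving_channels(
            cfg, 600, 120, 0.05, 0.05, mc, mf
        )
        dists = comovement.frame_distances(mrna, ribo)
        dd = comovement.normalized_distance_distribution(dists, 0.107, 3.0)
        near = dd.density[dd.bin_centers < 3 * 0.107].mean()
        baseline = np.median(dd.density[dd.bin_centers > 1.0])
        assert near > 3 * baseline

    def test_shuffled_ribosome_frames_flatten_the_peak(self):
        # permutation null: destroying temporal correspondence removes
        # the short-distance excess
        cfg = simkit.SimConfig(rng_seed=2, field_size=(30, 30),
                               localization_sd=0.01, mean_track_length=10)
        mc = simkit.MotionSpec(kind="two_state", D1=0.4, D2=0.1, k12=2.0, k21=0.77)
        mf = simkit.MotionSpec(kind="brownian", D=0.4)
        mrna, ribo, _ = simkit.simulate_comoving_channels(
            cfg, 400, 80, 0.05, 0.05, mc, mf
        )
        rng = np.random.default_rng(3)
        shuffled = ribo.copy()
        shuffled["x_um"] = rng.permutation(shuffled.x_um.to_numpy())
        shuffled["y_um"] = rng.permutation(shuffled.y_um.to_numpy())
        dd = comovement.normalized_distance_distribution(
            comovement.frame_distances(mrna, shuffled), 0.15, 2.0
        )
        _, p = comovement.flatness_test(dd)
        assert p > 0.01


def brute_force_comoving(frames_close, min_frames=3):
    """Oracle: does any run of >= min_frames consecutive close frames exist?"""
    best = 0
    for f in frames_close:
        run = 1
        while f + run in frames_close:
            run += 1
        best = max(best, run)
    return best >= min_frames


class TestFindComoving:
    def _two_tracks(self, close_frames, all_frames=range(8), d_far=5.0):
        m = track_at(list(all_frames), [0.0, 0.0])
        pos = np.array([
            [0.1, 0.0] if f in close_frames else [d_far, 0.0] for f in all_frames
        ])
        r = make_track(pos, track_id=1, channel="r", frames=list(all_frames))
        return m, r

    def test_three_consecutive_close_frames_qualify(self):
        m, r = self._two_tracks({2, 3, 4})
        pairs = comovement.find_comoving(m, r)
        assert len(pairs) == 1
        assert (pairs[0].start_frame, pairs[0].end_frame) == (2, 4)

    def test_two_consecutive_frames_do_not_qualify(self):
        m, r = self._two_tracks({2, 3})
        assert comovement.find_comoving(m, r) == []

    def test_broken_run_1_2_4_5_does_not_qualify(self):
        m, r = self._two_tracks({1, 2, 4, 5})
        assert comovement.find_comoving(m, r) == []

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.sets(st.integers(0, 9)))
    def test_run_criterion_matches_brute_force(self, close_frames):
        m, r = self._two_tracks(close_frames, all_frames=range(10))
        found = bool(comovement.find_comoving(m, r))
        assert found == brute_force_comoving(close_frames)

    def test_zero_offset_partners_all_found(self):
        cfg = simkit.SimConfig(rng_seed=4, mean_track_length=8)
        mc = simkit.MotionSpec(kind="brownian", D=0.2)
        mrna, ribo, gt = simkit.simulate_comoving_channels(
            cfg, 150, 150, 1.0, 0.0, mc, mc
        )
        pairs = comovement.find_comoving(mrna, ribo)
        found = {(p.mrna_track_id, p.ribo_track_id) for p in pairs}
        eligible = {
            (rec.mrna_id, rec.ribo_id) for rec in gt.pairs.itertuples()
            if rec.end_frame - rec.start_frame + 1 >= 3
        }
        assert eligible  # the scenario produces long-enough pairs
        assert eligible <= found

    def test_detection_symmetric_under_channel_swap(self):
        cfg = simkit.SimConfig(rng_seed=5, mean_track_length=8)
        mc = simkit.MotionSpec(kind="brownian", D=0.3)
        mrna, ribo, _ = simkit.simulate_comoving_channels(
            cfg, 60, 60, 0.3, 0.05, mc, mc
        )
        fwd = {(p.mrna_track_id, p.ribo_track_id)
               for p in comovement.find_comoving(mrna, ribo)}
        rev = {(p.ribo_track_id, p.mrna_track_id)
               for p in comovement.find_comoving(ribo, mrna)}
        assert fwd == rev

    def test_monotone_in_dmax_and_min_frames(self):
        cfg = simkit.SimConfig(rng_seed=6, mean_track_length=8)
        mc = simkit.MotionSpec(kind="brownian", D=0.3)
        mrna, ribo, _ = simkit.simulate_comoving_channels(
            cfg, 80, 80, 0.3, 0.08, mc, mc
        )
        def pairset(d_max, min_frames):
            return {(p.mrna_track_id, p.ribo_track_id) for p in
                    comovement.find_comoving(mrna, ribo, d_max, min_frames)}
        assert pairset(0.2, 3) <= pairset(0.32, 3) <= pairset(0.5, 3)
        assert pairset(0.32, 4) <= pairset(0.32, 3)

    def test_false_pair_rate_below_one_percent_at_low_density(self):
        # Monte-Carlo false-positive oracle: independent channels,
        # 30×30 μm field, ≤10 ribosome detections per frame
        cfg = simkit.SimConfig(rng_seed=7, field_size=(30, 30),
                               mean_track_length=6.2, n_frames=500)
        mrna, _ = simkit.simulate_tracks(
            cfg, simkit.MotionSpec(kind="brownian", D=0.3), 300, channel="mrna"
        )
        cfg2 = simkit.SimConfig(rng_seed=8, field_size=(30, 30),
                                mean_track_length=6.2, n_frames=500)
        ribo, _ = simkit.simulate_tracks(
            cfg2, simkit.MotionSpec(kind="brownian", D=0.3), 800, channel="ribo"
        )
        assert ribo.groupby("frame").size().mean() <= 10
        pairs = comovement.find_comoving(mrna, ribo)
        false_mrna = {p.mrna_track_id for p in pairs}
        assert len(false_mrna) / mrna.track_id.nunique() < 0.01


class TestSubsetAnalysis:
    def test_comoving_subset_is_slower(self):
        cfg = simkit.SimConfig(rng_seed=9, field_size=(30, 30),
                               localization_sd=0.01, mean_track_length=12)
        mc = simkit.MotionSpec(kind="two_state", D1=0.4, D2=0.1, k12=2.0, k21=2.0)
        mf = simkit.MotionSpec(kind="brownian", D=0.4)
        mrna, ribo, _ = simkit.simulate_comoving_channels(
            cfg, 800, 160, 0.15, 0.05, mc, mf
        )
        pairs = comovement.find_comoving(mrna, ribo)
        rep = comovement.comoving_subset_analysis(
            pairs, mrna, ribo, DT, fix_D=(0.1, 0.4)
        )
        co = rep["mrna_comoving"]
        free = rep["mrna_free"]
        assert not co["underpowered"]
        assert co["fit_one"].D_app < free["fit_one"].D_app
        if "fit_two" in co and "fit_two" in free:
            assert co["fit_two"].A > free["fit_two"].A

    def test_no_pairs_gives_empty_comoving_report(self):
        cfg = simkit.SimConfig(rng_seed=10, mean_track_length=8)
        mf = simkit.MotionSpec(kind="brownian", D=0.4)
        mrna, ribo, _ = simkit.simulate_comoving_channels(
            cfg, 60, 30, 0.0, 0.05, mf, mf
        )
        rep = comovement.comoving_subset_analysis([], mrna, ribo, DT)
        assert rep["mrna_comoving"]["n_tracks"] == 0
        assert rep["mrna_comoving"]["underpowered"]
        assert rep["mrna_free"]["n_tracks"] == mrna.track_id.nunique()
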
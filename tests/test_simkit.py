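"""Generator-level checks: closed-form moments, ground truth, rendering."""

import numpy as np
import pandas as pd
import pytest

from sptmap import diffusion, simkit
from sptmap.errors import ConfigurationError
from tests.conftest import DT


class TestSimulateTracks:
    def test_zero_diffusion_zero_noise_is_stationary(self):
        cfg = simkit.SimConfig(rng_seed=0, localization_sd=0.0)
        tracks, _ = simkit.simulate_tracks(
            cfg, simkit.MotionSpec(kind="brownian", D=0.0), 20, track_length=10
        )
        d = diffusion.collect_displacements(tracks, 1, DT)
        assert np.all(d.values == 0.0)

    def test_brownian_msd_matches_4_D_dt(self, brownian_tracks):
        # 2-D Brownian motion: E[r²] over one frame = 4·D·Δt
        tracks, _ = brownian_tracks
        d = diffusion.collect_displacements(tracks, 1, DT)
        assert len(d) == 100_000
        r2 = np.square(d.values)
        expected = 4 * 0.19 * DT
        se = r2.std(ddof=1) / np.sqrt(len(r2))
        assert abs(r2.mean() - expected) < 3 * se

    def test_two_state_without_switching_stays_in_state_one(self):
        cfg = simkit.SimConfig(rng_seed=1, localization_sd=0.0)
        spec = simkit.MotionSpec(kind="two_state", D1=0.4, D2=0.1, k12=0.0, k21=0.0)
        _, gt = simkit.simulate_tracks(cfg, spec, 50, track_length=20)
        assert (gt.steps.state == 1).all()

    def test_two_state_occupancy_matches_rate_ratio(self):
        cfg = simkit.SimConfig(rng_seed=2, localization_sd=0.0)
        spec = simkit.MotionSpec(kind="two_state", D1=0.4, D2=0.1, k12=2.0, k21=1.0)
        _, gt = simkit.simulate_tracks(cfg, spec, 300, track_length=101)
        frac2 = (gt.steps.state == 2).mean()
        p = 2.0 / 3.0
        n_eff = gt.steps.track_id.nunique() * 10  # steps are autocorrelated
        assert abs(frac2 - p) < 3 * np.sqrt(p * (1 - p) / n_eff)

    def test_track_lengths_geometric_with_configured_mean(self):
        cfg = simkit.SimConfig(
            rng_seed=3, mean_track_length=6.2, n_frames=10_000
        )
        tracks, _ = simkit.simulate_tracks(
            cfg, simkit.MotionSpec(kind="brownian", D=0.1), 3000
        )
        lengths = tracks.groupby("track_id").size()
        assert lengths.min() >= 1
        sem = lengths.std() / np.sqrt(len(lengths))
        assert abs(lengths.mean() - 6.2) < 4 * sem

    def test_same_seed_reproduces_identical_tracks(self):
        cfg = simkit.SimConfig(rng_seed=9)
        spec = simkit.MotionSpec(kind="two_state", D1=0.4, D2=0.1)
        a, _ = simkit.simulate_tracks(cfg, spec, 30)
        b, _ = simkit.simulate_tracks(cfg, spec, 30)
        pd.testing.assert_frame_equal(a, b)

    def test_confined_tracks_stay_inside_their_corral(self):
        cfg = simkit.SimConfig(rng_seed=4, localization_sd=0.0)
        L = 0.5
        tracks, gt = simkit.simulate_tracks(
            cfg, simkit.MotionSpec(kind="confined", D_in=0.4, corral_side=L),
            50, track_length=60,
        )
        for rec in gt.tracks.itertuples():
            sub = tracks[tracks.track_id == rec.track_id]
            assert (sub.x_um >= rec.corral_x - 1e-9).all()
            assert (sub.x_um <= rec.corral_x + L + 1e-9).all()
            assert (sub.y_um >= rec.corral_y - 1e-9).all()
            assert (sub.y_um <= rec.corral_y + L + 1e-9).all()

    def test_tethered_tracks_jitter_about_their_anchor(self):
        cfg = simkit.SimConfig(rng_seed=5, localization_sd=0.0)
        tracks, gt = simkit.simulate_tracks(
            cfg, simkit.MotionSpec(kind="tethered", tether_sd=0.02),
            20, track_length=50,
        )
        merged = tracks.merge(gt.tracks, on="track_id")
        r = np.hypot(merged.x_um - merged.anchor_x, merged.y_um - merged.anchor_y)
        assert r.max() < 0.2  # 10 sd

    def test_invalid_motion_rejected(self):
        cfg = simkit.SimConfig()
        with pytest.raises(ConfigurationError):
            simkit.simulate_tracks(
                cfg, simkit.MotionSpec(kind="two_state", D1=0.1, D2=0.4), 5
            )
        with pytest.raises(ConfigurationError):
            simkit.simulate_tracks(cfg, simkit.MotionSpec(kind="brownian", D=-1), 5)


class TestAdhesionField:
    def test_null_geometry_is_statistically_indistinguishable(self):
        from scipy import stats

        cfg = simkit.SimConfig(rng_seed=6, localization_sd=0.0, field_size=(15, 15))
        tracks, mask, gt = simkit.simulate_adhesion_field(
            cfg, 5, 1.5, D_near=0.3, D_far=0.3,
            n_tracks=400, inside_fraction=0.5, track_length=15,
        )
        D = diffusion.apparent_D_table(tracks, DT)
        inside = gt.tracks[gt.tracks.start_inside].track_id
        a = D[D.index.isin(inside)]
        b = D[~D.index.isin(inside)]
        assert stats.ks_2samp(a, b).pvalue > 0.01

    def test_slow_zones_slow_the_inside_population(self):
        from scipy import stats

        cfg = simkit.SimConfig(rng_seed=7, localization_sd=0.0, field_size=(15, 15))
        tracks, mask, gt = simkit.simulate_adhesion_field(
            cfg, 5, 2.0, D_near=0.1, D_far=0.4,
            n_tracks=400, inside_fraction=0.5, track_length=15,
        )
        D = diffusion.apparent_D_table(tracks, DT)
        inside = gt.tracks[gt.tracks.start_inside].track_id
        a = D[D.index.isin(inside)]
        b = D[~D.index.isin(inside)]
        assert len(a) >= 150 and len(b) >= 150
        assert a.mean() < b.mean()
        assert stats.mannwhitneyu(a, b, alternative="less").pvalue < 0.01

    def test_no_adhesions_gives_empty_mask(self):
        cfg = simkit.SimConfig(rng_seed=8, field_size=(10, 10))
        _, mask, _ = simkit.simulate_adhesion_field(
            cfg, 0, 1.0, D_near=0.1, D_far=0.4, n_tracks=10
        )
        assert not mask.any()

    def test_impossible_packing_raises(self):
        cfg = simkit.SimConfig(rng_seed=9, field_size=(3, 3))
        with pytest.raises(ConfigurationError):
            simkit.simulate_adhesion_field(cfg, 50, 2.0, 0.1, 0.4, n_tracks=5)


class TestComovingChannels:
    def _motions(self):
        return (
            simkit.MotionSpec(kind="two_state", D1=0.4, D2=0.1, k12=2.0, k21=0.77),
            simkit.MotionSpec(kind="brownian", D=0.4),
        )

    def test_zero_fraction_yields_no_pairs(self):
        mc, mf = self._motions()
        cfg = simkit.SimConfig(rng_seed=10)
        _, _, gt = simkit.simulate_comoving_channels(cfg, 50, 20, 0.0, 0.05, mc, mf)
        assert gt.pairs.empty

    def test_zero_jitter_partner_shadows_exactly(self):
        mc, mf = self._motions()
        cfg = simkit.SimConfig(rng_seed=11)
        mrna, ribo, gt = simkit.simulate_comoving_channels(
            cfg, 20, 20, 1.0, 0.0, mc, mf
        )
        for rec in gt.pairs.itertuples():
            m = mrna[mrna.track_id == rec.mrna_id].reset_index()
            r = ribo[ribo.track_id == rec.ribo_id].reset_index()
            assert np.allclose(m[["x_um", "y_um"]], r[["x_um", "y_um"]])

    def test_expected_pair_count_arithmetic(self):
        assert simkit.expected_pair_count(9000, 0.05) == pytest.approx(450)

    def test_insufficient_ribosomes_raises(self):
        mc, mf = self._motions()
        cfg = simkit.SimConfig(rng_seed=12)
        with pytest.raises(ConfigurationError):
            simkit.simulate_comoving_channels(cfg, 100, 0, 1.0, 0.0, mc, mf)


class TestRenderMovie:
    def test_empty_trackset_renders_pure_background(self):
        from sptmap.io import empty_tracks

        cfg = simkit.SimConfig(rng_seed=13, field_size=(3, 3), n_frames=4)
        movie = simkit.render_movie(empty_tracks(), 1.1, 500, 50, cfg)
        assert movie.shape == (4, 28, 28)
        assert abs(movie.mean() - 50) < 2  # Poisson mean preserved

    def test_stationary_spot_argmax_at_rendered_pixel(self):
        pos = pd.DataFrame(
            {"track_id": 0, "frame": [0], "x_um": [12 * 0.107],
             "y_um": [17 * 0.107], "channel": "c"}
        )
        cfg = simkit.SimConfig(rng_seed=14, field_size=(3.2, 3.2), n_frames=1)
        movie = simkit.render_movie(pos, 1.1, 1000, 0, cfg, noise=False)
        iy, ix = np.unravel_index(np.argmax(movie[0]), movie[0].shape)
        assert (ix, iy) == (12, 17)

    def test_out_of_field_positions_warn_and_clip(self):
        pos = pd.DataFrame(
            {"track_id": 0, "frame": [0], "x_um": [-5.0], "y_um": [1.0],
             "channel": "c"}
        )
        cfg = simkit.SimConfig(rng_seed=15, field_size=(3, 3), n_frames=1)
        with pytest.warns(UserWarning, match="clipped"):
            simkit.render_movie(pos, 1.1, 500, 10, cfg)
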
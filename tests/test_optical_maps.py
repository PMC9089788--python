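"""Activation, upstroke and APD maps against analytic fixtures and ground truth."""

import math
from dataclasses import replace

import numpy as np
import pytest

from atriakit import presets
from atriakit.optical_maps import (
    activation_map,
    apd_map,
    isochrone_contours,
    roi_summary,
    upstroke_velocity_map,
)
from atriakit.optical_prep import EnsembleConfig, prepare_beat
from atriakit.synth import generate_optical_movie
from conftest import make_beat


def _single_pixel_beat(values, dt):
    return make_beat(np.asarray(values, float)[:, None, None], frame_interval=dt)


class TestApdAnalyticOracles:
    def test_triangle_fixture_apd75_is_30ms(self):
        # instant rise to 1 at t=10 ms, linear fall to 0 at t=50 ms: the 0.25
        # level is crossed at t=40, so APD_75 = 30 ms.  Sampled finely so the
        # one-sample upstroke pins the max-slope instant at 10 ms.
        dt = 0.01
        t = np.arange(0.0, 60.0, dt)
        v = np.clip(1.0 - (t - 10.0) / 40.0, 0.0, None) * (t >= 10.0)
        apd = apd_map(_single_pixel_beat(v, dt), level=0.75)
        assert apd.apd[0, 0] == pytest.approx(30.0, abs=0.02)

    def test_square_pulse_apd_equals_duration(self):
        dt = 0.01
        t = np.arange(0.0, 60.0, dt)
        v = ((t >= 10.0) & (t < 30.0)).astype(float)
        apd = apd_map(_single_pixel_beat(v, dt), level=0.75)
        assert apd.apd[0, 0] == pytest.approx(20.0, abs=0.02)

    def test_exponential_recovery_apd_is_tau_ln4(self):
        tau, dt = 15.0, 1.0
        t = np.arange(0.0, 100.0, dt)
        v = np.where(t >= 10.0, np.exp(-(t - 10.0) / tau), 0.0)
        apd = apd_map(_single_pixel_beat(v, dt), level=0.75)
        assert apd.apd[0, 0] == pytest.approx(tau * math.log(4.0), abs=dt)

    def test_unrecovered_trace_flagged_nan(self):
        v = np.concatenate([np.zeros(10), np.ones(90)])   # never repolarizes
        apd = apd_map(_single_pixel_beat(v, 1.0))
        assert np.isnan(apd.apd[0, 0])
        assert apd.quality["n_no_recovery"] == 1


class TestUpstrokeVelocity:
    def test_linear_two_ms_rise_slope_half(self):
        v = np.concatenate([np.zeros(10), [0.5], np.ones(10),
                            np.linspace(1, 0, 30), np.zeros(10)])
        slope, mean_slope = upstroke_velocity_map(_single_pixel_beat(v, 1.0))
        assert slope[0, 0] == pytest.approx(0.50)
        assert mean_slope == pytest.approx(0.50)

    def test_one_frame_rise_capped_by_sampling(self):
        v = np.concatenate([np.zeros(10), np.ones(20), np.linspace(1, 0, 20)])
        slope, _ = upstroke_velocity_map(_single_pixel_beat(v, 1.0))
        assert slope[0, 0] == pytest.approx(1.0)


class TestActivationMap:
    def test_noiseless_planar_span_matches_field_crossing_time(self):
        # pixel centres spanning exactly 4 mm (81 columns at 50 um) crossed at
        # 0.5 mm/ms: max-min activation spread is 8 ms
        p = presets.con_optical(grid_size=(80, 81), noise_sd=0.0)
        movie, _ = generate_optical_movie(p, seed=0)
        beat = prepare_beat(movie, EnsembleConfig(smoothing_kernel=1))
        act = activation_map(beat, span_method="minmax")
        assert act.activation_span == pytest.approx(8.0, abs=0.1)

    def test_simultaneous_activation_span_zero(self):
        p = presets.con_optical(grid_size=(16, 16), pacing_site=(8, 0),
                                conduction_velocity=math.inf, noise_sd=0.0)
        movie, _ = generate_optical_movie(p, seed=0)
        act = activation_map(prepare_beat(movie), span_method="minmax")
        assert act.activation_span == pytest.approx(0.0, abs=0.05)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(3)
        base = np.zeros((100, 4, 4))
        onset = 20
        for r in range(4):
            for c in range(4):
                t0 = onset + r + c
                base[t0:t0 + 2, r, c] = [0.5, 1.0]
                base[t0 + 2:, r, c] = np.exp(-(np.arange(98 - t0)) / 20.0)
        shifted = np.roll(base, 7, axis=0)
        t1 = activation_map(make_beat(base)).t_act
        t2 = activation_map(make_beat(shifted)).t_act
        assert np.allclose(t2 - t1, 7.0, atol=1e-9)

    def test_garbage_trace_rejected_and_counted(self):
        good = np.concatenate([np.zeros(10), [0.5], np.ones(10),
                               np.linspace(1, 0, 29)])
        accel = (np.arange(50) / 49.0) ** 2       # derivative max at window end
        traces = np.stack([accel, good], axis=1)[:, :, None]
        act = activation_map(make_beat(traces))
        assert np.isnan(act.t_act[0, 0])
        assert act.quality["n_edge_rejected"] == 1
        assert np.isfinite(act.t_act[1, 0])


class TestRecoveryAgainstGroundTruth:
    def test_noiseless_per_pixel_recovery_within_one_frame(self, con_movie_noiseless):
        movie, truth = con_movie_noiseless
        beat = prepare_beat(movie)
        act = activation_map(beat)
        apd = apd_map(beat)
        act_err = np.abs(act.t_act - truth.activation_delay)
        apd_err = np.abs(apd.apd - truth.apd75)
        assert np.mean(act_err < movie.frame_interval) >= 0.99
        assert np.mean(apd_err < movie.frame_interval) >= 0.99

    def test_apd_invariant_to_amplitude_rescaling(self, small_optical_preset):
        from atriakit.optical_prep import normalize_invert, segment_beats, \
            ensemble_average, spatial_smooth
        movie, _ = generate_optical_movie(
            replace(small_optical_preset, noise_sd=0.0), seed=0)
        stack = spatial_smooth(ensemble_average(movie, segment_beats(movie)),
                               movie.roi)
        gain = 1.0 + np.arange(16)[None, :] / 8.0     # per-pixel gain gradient
        b1 = normalize_invert(stack, movie.polarity, movie.roi, 1.0)
        base = float(stack[-5:].mean())
        b2 = normalize_invert((stack - base) * gain[None] + base, movie.polarity,
                              movie.roi, 1.0)
        assert np.allclose(apd_map(b1).apd, apd_map(b2).apd,
                           atol=1e-6, equal_nan=True)


class TestSummariesAndIsochrones:
    def test_single_pixel_region_summary_equals_pixel(self, con_movie_noiseless):
        movie, _ = con_movie_noiseless
        beat = prepare_beat(movie)
        region = np.zeros((80, 80), bool)
        region[40, 40] = True
        s = roi_summary(beat, region_label="one", region=region)
        assert s.n_roi_pixels == 1
        apd = apd_map(beat)
        assert s.mean_apd75 == pytest.approx(apd.apd[40, 40])

    def test_disjoint_regions_are_independent(self, con_movie_noiseless):
        movie, _ = con_movie_noiseless
        beat = prepare_beat(movie)
        left = np.zeros((80, 80), bool)
        left[:, :20] = True
        right = np.zeros((80, 80), bool)
        right[:, 60:] = True
        s_l = roi_summary(beat, "LA", region=left)
        s_r = roi_summary(beat, "LV", region=right)
        assert s_l.n_roi_pixels == s_r.n_roi_pixels == 1600
        # the downstream region activates later on average but shares APD truth
        assert s_r.activation_span == pytest.approx(s_l.activation_span, abs=0.5)
        assert s_l.mean_apd75 == pytest.approx(s_r.mean_apd75, abs=0.5)

    def test_point_stimulus_isochrones_monotone_in_radius(self, tmp_path):
        p = presets.con_optical(grid_size=(24, 24), pacing_site=(12, 12),
                                wave_geometry="point", noise_sd=0.0)
        movie, truth = generate_optical_movie(p, seed=0)
        act = activation_map(prepare_beat(movie))
        rr, cc = np.mgrid[0:24, 0:24]
        radius = np.hypot(rr - 12, cc - 12).ravel()
        t = act.t_act.ravel()
        order = np.argsort(radius)
        good = np.isfinite(t[order])
        # binned mean activation must increase with radius
        binned = [t[order][good][i:i + 40].mean()
                  for i in range(0, good.sum() - 40, 40)]
        assert np.all(np.diff(binned) > -0.05)
        levels = isochrone_contours(act, out_png=tmp_path / "iso.png")
        assert (tmp_path / "iso.png").exists()
        assert np.all(np.diff(levels) > 0)
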
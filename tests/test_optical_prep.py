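"""Segmentation, ensemble averaging, spatial smoothing, normalization."""

import math
from dataclasses import replace

import numpy as np
import pytest

from atriakit import presets
from atriakit.errors import ConfigurationError, InsufficientBeatsError, NoSignalError
from atriakit.io import VoltageMovie
from atriakit.optical_prep import (
    EnsembleConfig,
    ensemble_average,
    normalize_invert,
    prepare_beat,
    segment_beats,
    spatial_smooth,
)
from atriakit.synth import generate_optical_movie


def _movie_from(frames, stim, dt=1.0, polarity=presets.POLARITY_INCREASES):
    frames = np.asarray(frames)
    return VoltageMovie(frames=frames, frame_interval=dt, pixel_pitch=0.05,
                        stimulus_times=np.asarray(stim, float), polarity=polarity,
                        roi=np.ones(frames.shape[1:], dtype=bool))


class TestSegmentBeats:
    def test_complete_window_count(self):
        # 1000 frames at 1 ms with stimuli every 100 ms from 50 ms: the last
        # window (950-1050 ms) is incomplete, leaving 9
        movie = _movie_from(np.zeros((1000, 4, 4), np.uint16),
                            np.arange(50, 1000, 100))
        windows = segment_beats(movie)
        assert len(windows) == 9
        assert [a for a, _ in windows] == list(range(50, 950, 100))
        assert all(b - a == 100 for a, b in windows)

    def test_insufficient_beats_error(self):
        movie = _movie_from(np.zeros((520, 4, 4), np.uint16),
                            np.arange(20, 520, 100))
        with pytest.raises(InsufficientBeatsError):
            segment_beats(movie, EnsembleConfig(n_beats_to_average=8))

    def test_stimuli_detected_from_mean_trace(self, small_optical_preset):
        # one extra beat: detection-based windows start an upstroke later than
        # the stimuli, so the final cycle is incomplete
        movie, _ = generate_optical_movie(
            replace(small_optical_preset, noise_sd=0.0, n_beats=10), seed=0)
        blind = VoltageMovie(frames=movie.frames, frame_interval=1.0,
                             pixel_pitch=0.05, stimulus_times=np.empty(0),
                             polarity=movie.polarity, roi=movie.roi)
        windows = segment_beats(blind)
        assert len(windows) >= 8
        starts = np.array([a for a, _ in windows], float)
        # detected upstrokes sit a conduction delay after the true stimuli
        true = movie.stimulus_times[:len(starts)]
        assert np.all(np.abs(starts - true) < 10.0)


class TestEnsembleAverage:
    def test_identical_beats_average_to_one_beat(self, small_optical_preset):
        movie, _ = generate_optical_movie(
            replace(small_optical_preset, noise_sd=0.0), seed=0)
        windows = segment_beats(movie)
        avg = ensemble_average(movie, windows)
        a, b = windows[0]
        assert np.allclose(avg, movie.frames[a:b].astype(float))

    def test_single_beat_identity(self, small_optical_preset):
        movie, _ = generate_optical_movie(small_optical_preset, seed=1)
        windows = segment_beats(movie)
        avg = ensemble_average(movie, windows, EnsembleConfig(n_beats_to_average=1))
        a, b = windows[0]
        assert np.array_equal(avg, movie.frames[a:b].astype(float))

    def test_noise_shrinks_by_sqrt_8(self, small_optical_preset):
        # CLT oracle: averaging 8 i.i.d.-noise beats divides the noise sd by sqrt(8)
        p = replace(small_optical_preset, noise_sd=30.0)
        noisy, _ = generate_optical_movie(p, seed=6)
        clean, _ = generate_optical_movie(replace(p, noise_sd=0.0), seed=6)
        w = segment_beats(noisy)
        resid = ensemble_average(noisy, w) - ensemble_average(clean, w)
        assert resid.size >= 1e4
        assert np.std(resid) == pytest.approx(30.0 / math.sqrt(8), rel=0.10)


class TestSpatialSmooth:
    def test_impulse_response_is_kernel_mean(self):
        frame = np.zeros((1, 11, 11))
        frame[0, 5, 5] = 25.0
        out = spatial_smooth(frame, np.ones((11, 11), bool))
        assert np.allclose(out[0, 3:8, 3:8], 1.0)
        assert out[0, 2, 5] == 0.0

    def test_constant_frame_unchanged_and_kernel_one_identity(self):
        frame = np.full((3, 9, 9), 7.0)
        roi = np.ones((9, 9), bool)
        assert np.allclose(spatial_smooth(frame, roi), 7.0)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(2, 9, 9))
        assert np.allclose(spatial_smooth(x, roi, EnsembleConfig(smoothing_kernel=1)), x)

    def test_roi_aware_mean_excludes_outside_pixels(self):
        frame = np.full((1, 9, 9), 2.0)
        roi = np.ones((9, 9), bool)
        roi[:, :4] = False
        out = spatial_smooth(frame, roi)
        # in-ROI values are unaffected by masked neighbours, outside is NaN
        assert np.allclose(out[0, :, 4:], 2.0)
        assert np.isnan(out[0, :, :4]).all()

    def test_kernel_larger_than_frame_rejected(self):
        with pytest.raises(ConfigurationError):
            spatial_smooth(np.zeros((1, 3, 3)), np.ones((3, 3), bool))

    def test_kernel_must_be_odd(self):
        with pytest.raises(ConfigurationError):
            EnsembleConfig(smoothing_kernel=4)


class TestNormalizeInvert:
    def test_noiseless_pixel_peaks_at_one_rests_at_zero(self, con_movie_noiseless):
        movie, _ = con_movie_noiseless
        beat = prepare_beat(movie, EnsembleConfig(smoothing_kernel=1))
        tr = beat.traces[:, 40, 40]
        assert np.nanmax(tr) == pytest.approx(1.0)
        assert abs(tr[-1]) < 1e-6               # diastolic tail at baseline
        assert np.nanmin(tr) > -0.2

    def test_flat_pixel_dropped_from_roi(self):
        stack = np.zeros((100, 5, 5))
        stack[20:40, :, :2] = 50.0              # only two columns carry signal
        roi = np.ones((5, 5), bool)
        beat = normalize_invert(stack, presets.POLARITY_INCREASES, roi, 1.0)
        assert beat.roi[:, :2].all() and not beat.roi[:, 2:].any()
        assert np.isnan(beat.traces[:, 0, 4]).all()

    def test_all_flat_raises_no_signal(self):
        stack = np.zeros((50, 4, 4))
        with pytest.raises(NoSignalError):
            normalize_invert(stack, presets.POLARITY_INCREASES,
                             np.ones((4, 4), bool), 1.0)

    def test_polarity_contract(self, small_optical_preset):
        # bright-on-depolarization movies must not be inverted
        p = replace(small_optical_preset, noise_sd=0.0,
                    polarity=presets.POLARITY_INCREASES)
        movie, _ = generate_optical_movie(p, seed=0)
        beat = prepare_beat(movie)
        assert np.nanmax(beat.traces) == pytest.approx(1.0)
        assert np.nanmean(beat.traces[-5:]) < 0.05  # diastolic tail at baseline
        assert np.nanmin(beat.traces) > -0.05       # upstroke not flipped


class TestFullChain:
    def test_template_recovered_within_one_percent(self, con_movie_noiseless):
        movie, truth = con_movie_noiseless
        beat = prepare_beat(movie, EnsembleConfig(smoothing_kernel=1))
        dt = movie.frame_interval
        # at the 75%-repolarization instant the normalized trace crosses 0.25
        for (r, c) in [(40, 10), (40, 70), (10, 40)]:
            t_cross = truth.activation_delay[r, c] + truth.apd75[r, c]
            j = t_cross / dt
            lo, hi = int(np.floor(j)), int(np.ceil(j))
            v = np.interp(j, [lo, hi], [beat.traces[lo, r, c], beat.traces[hi, r, c]])
            assert v == pytest.approx(0.25, abs=0.01)

    def test_smoothing_commutes_with_normalization_for_uniform_wavefront(self):
        p = presets.con_optical(grid_size=(12, 12), pacing_site=(6, 0),
                                conduction_velocity=math.inf, noise_sd=0.0)
        movie, _ = generate_optical_movie(p, seed=0)
        windows = segment_beats(movie)
        stack = ensemble_average(movie, windows)
        a = normalize_invert(spatial_smooth(stack, movie.roi), movie.polarity,
                             movie.roi, 1.0)
        b_raw = normalize_invert(stack, movie.polarity, movie.roi, 1.0)
        b = spatial_smooth(b_raw.traces, b_raw.roi)
        assert np.allclose(a.traces, b, atol=1e-9, equal_nan=True)
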
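"""R detection, signal averaging, fiducial measurement, PAC labeling."""

import numpy as np
import pytest

from atriakit import presets
from atriakit.ecg_metrics import (
    BeatTable,
    detect_pac,
    detect_r_peaks,
    measure_intervals,
    measure_recording,
    signal_average,
)
from atriakit.errors import InsufficientSinusBeatsError
from atriakit.io import ECGRecording
from atriakit.synth import generate_ecg


class TestDetectRPeaks:
    def test_sinus_count_and_position_accuracy(self, con_ecg_60s):
        ecg, truth = con_ecg_60s
        beats = detect_r_peaks(ecg)
        assert abs(beats.n_beats - truth.beat_times.size) <= 1
        if beats.n_beats == truth.beat_times.size:
            err_ms = np.abs(beats.r_times - truth.beat_times) * 1000.0
            assert err_ms.max() <= 2.0

    def test_zero_signal_gives_empty_table(self):
        flat = ECGRecording(samples=np.zeros(20000), sampling_rate=2000.0)
        assert detect_r_peaks(flat).n_beats == 0

    def test_detection_during_af(self):
        ecg, truth = generate_ecg(presets.dko_ecg_af(), 60.0, seed=2)
        beats = detect_r_peaks(ecg)
        # QRS complexes are conducted (irregularly) throughout AF
        assert abs(beats.n_beats - truth.beat_times.size) <= 3


class TestSignalAverage:
    def test_identical_beats_average_to_one_beat(self):
        p = presets.con_ecg(noise_sd=0.0, rr_jitter=0.0)
        ecg, _ = generate_ecg(p, 10.0, seed=0)
        beats = detect_r_peaks(ecg)
        sab = signal_average(ecg, beats, n=10)
        sab2 = signal_average(ecg, beats, n=10, start_beat=15)
        assert np.allclose(sab.waveform, sab2.waveform, atol=1e-12)
        assert sab.n_beats_averaged == 10

    def test_noise_shrinks_by_sqrt_10(self):
        # CLT oracle on the averaged residual
        p = presets.con_ecg(noise_sd=0.05, rr_jitter=0.0)
        noisy, _ = generate_ecg(p, 10.0, seed=3)
        clean, _ = generate_ecg(presets.con_ecg(noise_sd=0.0, rr_jitter=0.0),
                                10.0, seed=3)
        beats = detect_r_peaks(clean)
        resid = signal_average(noisy, beats, n=10, start_beat=5).waveform \
            - signal_average(clean, beats, n=10, start_beat=5).waveform
        assert np.std(resid) == pytest.approx(0.05 / np.sqrt(10), rel=0.15)

    def test_af_only_recording_raises(self):
        p = presets.dko_ecg_af(af_episodes=[(0.5, 59.0)])
        ecg, _ = generate_ecg(p, 60.0, seed=1)
        beats = detect_r_peaks(ecg)
        from atriakit.rhythm import label_af_beats
        labeled = label_af_beats(beats, [(0.0, 60.0)])
        with pytest.raises(InsufficientSinusBeatsError):
            signal_average(ecg, labeled, n=10)


class TestMeasureIntervals:
    @pytest.mark.parametrize("factory", [presets.con_ecg, presets.dko_ecg_wk1],
                             ids=["control", "knockout_wk1"])
    def test_noiseless_recovery_within_1ms(self, factory):
        p = factory(noise_sd=0.0, rr_jitter=0.0)
        ecg, _ = generate_ecg(p, 30.0, seed=0)
        res = measure_recording(ecg, detect_r_peaks(ecg))
        assert res.p_duration == pytest.approx(p.p_duration, abs=1.0)
        assert res.pr_interval == pytest.approx(p.pr_interval, abs=1.0)
        assert res.qrs_duration == pytest.approx(p.qrs_duration, abs=1.0)
        assert res.heart_rate == pytest.approx(p.heart_rate, rel=0.01)

    def test_noise_robustness_under_0p05_mV(self):
        intervals = {}
        for sd in (0.0, 0.05):
            ecg, _ = generate_ecg(presets.con_ecg(noise_sd=sd, rr_jitter=0.0),
                                  30.0, seed=4)
            res = measure_recording(ecg, detect_r_peaks(ecg))
            intervals[sd] = (res.p_duration, res.pr_interval, res.qrs_duration)
        deltas = np.abs(np.array(intervals[0.05]) - np.array(intervals[0.0]))
        assert np.all(deltas < 2.0)

    def test_af_beat_has_no_p_and_is_flagged(self):
        # averaged AF beats carry no P deflection: NaN duration, flagged
        p = presets.con_ecg(noise_sd=0.005, p_amplitude=0.0)
        ecg, _ = generate_ecg(p, 15.0, seed=0)
        beats = detect_r_peaks(ecg)
        sab = signal_average(ecg, beats, n=10)
        res = measure_intervals(sab)
        assert np.isnan(res.p_duration)
        assert "no_p_deflection" in res.flags

    def test_fifty_tracings_quantified(self, con_ecg_60s):
        ecg, _ = con_ecg_60s
        res = measure_recording(ecg, detect_r_peaks(ecg))
        assert res.n_tracings == 50
        short, _ = generate_ecg(presets.con_ecg(), 5.0, seed=0)
        res_short = measure_recording(short, detect_r_peaks(short))
        assert res_short.n_tracings < 50
        assert any(f.startswith("only_") for f in res_short.flags)


class TestDetectPac:
    def _table(self, times_s):
        return BeatTable(r_times=np.asarray(times_s),
                         labels=np.full(len(times_s), "sinus", dtype=object))

    def test_constant_rr_no_pacs(self):
        beats = detect_pac(self._table(np.arange(20) * 0.12))
        assert not np.any(beats.labels == "PAC")

    def test_single_early_beat_is_one_pac(self):
        # one beat arrives at 60% of the cycle, later beats back on schedule
        t = list(np.arange(8) * 0.12)
        t += [t[-1] + 0.072]
        t += [t[-1] + 0.12 * k for k in range(1, 6)]
        beats = detect_pac(self._table(t))
        assert int(np.sum(beats.labels == "PAC")) == 1
        assert beats.labels[8] == "PAC"

    def test_af_precedence_over_pac(self):
        t = np.arange(20) * 0.12
        labels = np.full(20, "sinus", dtype=object)
        labels[10:15] = "in_AF"
        table = BeatTable(r_times=t, labels=labels)
        table.r_times[12] -= 0.05              # early beat inside AF
        beats = detect_pac(BeatTable(r_times=np.sort(table.r_times),
                                     labels=labels))
        assert not np.any(beats.labels == "PAC")
        assert np.all(beats.labels[10:15] == "in_AF")

    def test_generator_pacs_recovered(self):
        ecg, truth = generate_ecg(presets.dko_ecg_wk2_4(), 60.0, seed=8)
        beats = detect_pac(detect_r_peaks(ecg))
        assert int(np.sum(beats.labels == "PAC")) == \
            int(np.sum(truth.labels == "PAC"))
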
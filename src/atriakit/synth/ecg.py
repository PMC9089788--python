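"""Synthetic single-lead murine surface ECG with construction-time truth.

Beats are piecewise-linear / raised-cosine deflection templates (P, QRS, T)
placed at fiducials derived from the preset intervals.  Atrial-fibrillation
episodes replace P waves with continuous low-amplitude fibrillatory
oscillation and draw R-R intervals from a distribution with the preset
coefficient of variation.  Premature atrial complexes (PACs) are inserted as
early beats at a fixed coupling fraction of the mean R-R; when the preset
requests a heart-rate-variability multiple (``hr_sd_scale``) the post-PAC
pause is solved numerically so the 60-s HR standard deviation equals that
multiple of the analytic sinus value exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from ..errors import ConfigurationError
from ..io import ECGRecording
from ..presets import EcgPreset

SINUS, PAC, IN_AF = "sinus", "PAC", "in_AF"


@dataclass
class EcgGroundTruth:
    """Truth for one generated recording.  Times in seconds."""

    beat_times: np.ndarray                 # R-peak times, s
    labels: np.ndarray                     # per-beat {sinus, PAC, in_AF}
    fiducials: pd.DataFrame                # per-beat onset/offset times, s (NaN in AF)
    af_episodes: list = field(default_factory=list)   # (start_s, end_s)
    af_mask: np.ndarray | None = None      # bool per sample
    target_hr_sd: float = np.nan           # bpm, the constructed 60-s HR SD

    @property
    def rr_ms(self) -> np.ndarray:
        return np.diff(self.beat_times) * 1000.0


def analytic_hr_sd(preset: EcgPreset) -> float:
    """Delta-method SD of instantaneous HR (bpm) for pure sinus jitter."""
    rr0 = 60000.0 / preset.heart_rate
    return 60000.0 * preset.rr_jitter / rr0 ** 2


def _in_any_episode(t_s: float, episodes) -> bool:
    return any(start <= t_s < start + dur for start, dur in episodes)


def _build_rr_sequence(preset: EcgPreset, duration_s: float, rng: np.random.Generator):
    """Return (rr_ms list, labels list) for beats spanning the recording."""
    rr0 = 60000.0 / preset.heart_rate
    rr, labels = [], []
    t = rr0                                   # first R one cycle in
    times = [t]
    labels.append(SINUS)
    while True:
        if _in_any_episode(t / 1000.0, preset.af_episodes):
            mean = preset.af_rr_scale * rr0
            step = rng.normal(mean, preset.rr_irregularity * mean)
            step = max(step, 40.0)
        else:
            step = max(rng.normal(rr0, preset.rr_jitter), 20.0)
        if t + step > duration_s * 1000.0 - 1.0:
            break
        t += step
        rr.append(step)
        times.append(t)
        labels.append(IN_AF if _in_any_episode(t / 1000.0, preset.af_episodes) else SINUS)
    return np.asarray(times), np.asarray(rr), labels


def _insert_pacs(times, rr, labels, preset: EcgPreset, duration_s: float,
                 rng: np.random.Generator):
    """Convert selected sinus beats into PAC + pause pairs; solve the pause so
    the 60-s HR SD hits ``hr_sd_scale`` x the analytic sinus SD when asked."""
    rr0 = 60000.0 / preset.heart_rate
    n_pac = int(round(preset.pac_rate * duration_s / 60.0))
    if n_pac == 0:
        return times, rr, labels, analytic_hr_sd(preset) * preset.hr_sd_scale

    # candidate beats: sinus, not first/last few, not followed by AF
    candidates = [i for i in range(8, len(rr) - 2)
                  if labels[i + 1] == SINUS and labels[i] == SINUS
                  and labels[i + 2] == SINUS]
    n_pac = min(n_pac, len(candidates))   # AF-dominated recordings: place fewer
    if n_pac == 0:
        return times, rr, labels, np.nan
    picks = [candidates[int(j)] for j in
             np.linspace(0, len(candidates) - 1, n_pac + 2)[1:-1]]

    def assemble(pause_ms: float):
        rr2 = rr.copy().astype(float)
        lab2 = list(labels)
        for i in picks:
            rr2[i] = preset.pac_coupling * rr0       # interval ending at the PAC
            rr2[i + 1] = pause_ms                    # post-PAC pause
            lab2[i + 1] = PAC
        t2 = np.concatenate([[times[0]], times[0] + np.cumsum(rr2)])
        return t2, rr2, lab2

    target = preset.hr_sd_scale * analytic_hr_sd(preset)

    def hr_sd_of(pause_ms: float) -> float:
        t2, rr2, _ = assemble(pause_ms)
        win = t2[1:] <= min(duration_s, 60.0) * 1000.0
        hr = 60000.0 / rr2[win]
        return float(np.std(hr, ddof=1))

    solve = preset.hr_sd_scale > 1.0 and not preset.af_episodes
    pause = (2.0 - preset.pac_coupling) * rr0        # full compensatory default
    if solve:
        lo, hi = 1.0 * rr0, 2.4 * rr0
        if hr_sd_of(lo) >= target:
            pause = lo                               # already at/above target
        elif hr_sd_of(hi) <= target:
            pause = hi
        else:
            pause = brentq(lambda p: hr_sd_of(p) - target, lo, hi, xtol=1e-6)
    t2, rr2, lab2 = assemble(pause)
    # drop beats pushed past the end of the recording by lengthened pauses
    keep = t2 <= duration_s * 1000.0 - 1.0
    t2, lab2 = t2[keep], [l for l, k in zip(lab2, keep) if k]
    rr2 = np.diff(t2)
    return t2, rr2, lab2, (target if solve else np.nan)


def _add_triangle(v, fs, t0_ms, t_peak_ms, t1_ms, amp):
    """Add a piecewise-linear deflection rising t0->peak and falling peak->t1."""
    n = v.size
    i0 = max(int(np.ceil(t0_ms / 1000.0 * fs)), 0)
    i1 = min(int(np.floor(t1_ms / 1000.0 * fs)), n - 1)
    if i1 < i0:
        return
    tt = np.arange(i0, i1 + 1) / fs * 1000.0
    up = tt <= t_peak_ms
    seg = np.empty(tt.size)
    if t_peak_ms > t0_ms:
        seg[up] = amp * (tt[up] - t0_ms) / (t_peak_ms - t0_ms)
    else:
        seg[up] = amp
    if t1_ms > t_peak_ms:
        seg[~up] = amp * (t1_ms - tt[~up]) / (t1_ms - t_peak_ms)
    else:
        seg[~up] = amp
    v[i0:i1 + 1] += seg


def _add_raised_cosine(v, fs, t0_ms, width_ms, amp):
    n = v.size
    i0 = max(int(np.ceil(t0_ms / 1000.0 * fs)), 0)
    i1 = min(int(np.floor((t0_ms + width_ms) / 1000.0 * fs)), n - 1)
    if i1 < i0:
        return
    tt = np.arange(i0, i1 + 1) / fs * 1000.0
    v[i0:i1 + 1] += amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * (tt - t0_ms) / width_ms))


def _render_p_wave(v, fs, onset_ms, duration_ms, amp, morphology):
    if morphology == "double_peak":
        # two overlapping humps spanning exactly [onset, onset + duration]
        w = 0.6 * duration_ms
        _add_triangle(v, fs, onset_ms, onset_ms + w / 2.0, onset_ms + w, 0.8 * amp)
        o2 = onset_ms + duration_ms - w
        _add_triangle(v, fs, o2, o2 + w / 2.0, o2 + w, 0.8 * amp)
    else:
        _add_triangle(v, fs, onset_ms, onset_ms + duration_ms / 2.0,
                      onset_ms + duration_ms, amp)


def generate_ecg(preset: EcgPreset, duration: float, seed: int):
    """Render a recording of ``duration`` seconds.

    Returns ``(ECGRecording, EcgGroundTruth)``; reproducible per seed.
    """
    if duration < 1.0:
        raise ConfigurationError("duration must be >= 1 s")
    for start, dur in preset.af_episodes:
        if start + dur > duration:
            raise ConfigurationError("af episode extends beyond the recording")

    rng = np.random.default_rng(seed)
    fs = preset.sampling_rate
    n = int(round(duration * fs))
    v = np.zeros(n)

    times_ms, rr_ms, labels = _build_rr_sequence(preset, duration, rng)
    times_ms, rr_ms, labels, target_sd = _insert_pacs(
        times_ms, rr_ms, labels, preset, duration, rng)
    labels = np.asarray([
        IN_AF if _in_any_episode(t / 1000.0, preset.af_episodes) else l
        for t, l in zip(times_ms, labels)
    ])

    half_qrs = preset.qrs_duration / 2.0
    fid_rows = []
    for r, lab in zip(times_ms, labels):
        _add_triangle(v, fs, r - half_qrs, r, r + half_qrs, preset.qrs_amplitude)
        _add_raised_cosine(v, fs, r + half_qrs + preset.t_gap,
                           preset.t_width, preset.t_amplitude)
        q_on, q_off = r - half_qrs, r + half_qrs
        if lab == IN_AF:
            fid_rows.append((r / 1000.0, np.nan, np.nan,
                             q_on / 1000.0, q_off / 1000.0))
            continue
        p_on = q_on - preset.pr_interval
        p_amp = preset.p_amplitude * (0.6 if lab == PAC else 1.0)
        morph = "single_peak" if lab == PAC else preset.p_morphology
        _render_p_wave(v, fs, p_on, preset.p_duration, p_amp, morph)
        fid_rows.append((r / 1000.0, p_on / 1000.0,
                         (p_on + preset.p_duration) / 1000.0,
                         q_on / 1000.0, q_off / 1000.0))

    # fibrillatory waves: frequency-wandering oscillation over each episode
    t_s = np.arange(n) / fs
    af_mask = np.zeros(n, dtype=bool)
    for start, dur in preset.af_episodes:
        sel = (t_s >= start) & (t_s < start + dur)
        m = int(sel.sum())
        if m == 0:
            continue
        f_inst = preset.fwave_freq + np.clip(
            np.cumsum(rng.normal(0.0, 0.02, m)), -3.0, 3.0)
        phase = 2.0 * np.pi * np.cumsum(f_inst) / fs + rng.uniform(0, 2 * np.pi)
        v[sel] += preset.fwave_amplitude * np.sin(phase)
        af_mask |= sel

    if preset.noise_sd > 0:
        v = v + rng.normal(0.0, preset.noise_sd, n)

    ecg = ECGRecording(samples=v, sampling_rate=fs)
    fiducials = pd.DataFrame(
        fid_rows, columns=["r_s", "p_onset_s", "p_offset_s", "qrs_onset_s", "qrs_offset_s"])
    truth = EcgGroundTruth(
        beat_times=times_ms / 1000.0,
        labels=labels,
        fiducials=fiducials,
        af_episodes=[(s, s + d) for s, d in preset.af_episodes],
        af_mask=af_mask,
        target_hr_sd=target_sd,
    )
    return ecg, truth
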
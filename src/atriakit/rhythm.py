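"""Atrial-fibrillation classification and R-R variability.

The study's rule: spontaneous AF is disorganized atrial activity with
irregularly conducted QRS complexes lasting more than 30 s in at least 2
separate 1-minute recordings on the same day.  "Disorganized atrial
activity" is operationalized here as (a) R-R irregularity — the coefficient
of variation of R-R within a sliding window exceeds a threshold — AND (b)
the absence of a consistent pre-QRS P deflection (the beat-aligned median
waveform in the P window stays inside the k·sd noise band; random
fibrillatory waves cancel under the median, a repeating P wave does not).
Both thresholds are explicit, configurable artifact decisions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .ecg_metrics import IN_AF, BeatTable
from .errors import ConfigurationError
from .io import ECGRecording

log = logging.getLogger(__name__)


@dataclass
class AFCriteria:
    min_episode_s: float = 30.0            # episode must last MORE than this
    min_recordings_same_day: int = 2
    recording_length_s: float = 60.0
    rr_cv_threshold: float = 0.15
    window_s: float = 5.0
    step_s: float = 1.0
    p_band_k: float = 2.0                  # noise-band multiple for the P check
    p_window_ms: tuple[float, float] = (-50.0, -8.0)   # pre-QRS window rel. R

    def __post_init__(self) -> None:
        if self.min_episode_s > self.recording_length_s:
            raise ConfigurationError("min_episode_s must not exceed recording_length_s")
        for name in ("min_episode_s", "rr_cv_threshold", "window_s", "step_s"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")


@dataclass
class RhythmCall:
    """Per-recording episodes plus the per-animal-day diagnosis inputs."""

    episodes: list                          # (start_s, end_s), non-overlapping
    animal_day_af: bool = False
    hr_sd: float = np.nan                   # bpm
    rr_sd: float = np.nan                   # ms
    poincare_pairs: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))


def _noise_sd(ecg: ECGRecording) -> float:
    """Robust high-frequency noise estimate (MAD of the differenced trace)."""
    d = np.diff(ecg.samples)
    return 1.4826 * float(np.median(np.abs(d - np.median(d)))) / np.sqrt(2.0)


def _median_p_amplitude(ecg: ECGRecording, r_times: np.ndarray,
                        window_ms: tuple[float, float]) -> float:
    """Peak |median across beats| of the beat-aligned pre-QRS segment."""
    fs = ecg.sampling_rate
    lo = int(round(window_ms[0] / 1000.0 * fs))
    hi = int(round(window_ms[1] / 1000.0 * fs))
    segs = []
    for r in r_times:
        i = int(round(r * fs))
        if i + lo < 0 or i + hi >= ecg.samples.size:
            continue
        segs.append(ecg.samples[i + lo:i + hi + 1])
    if len(segs) < 3:
        return np.inf                       # too few beats: do not call AF
    med = np.median(np.asarray(segs), axis=0)
    return float(np.max(np.abs(med - np.median(med))))


def detect_af_episodes(ecg: ECGRecording, beats: BeatTable,
                       criteria: AFCriteria | None = None) -> list:
    """Sliding-window AF flagging, merged into episodes longer than the rule.

    Returns (start_s, end_s) intervals with duration > ``min_episode_s``.
    A recording shorter than one window yields an empty list with a warning.
    """
    criteria = criteria or AFCriteria()
    w, step = criteria.window_s, criteria.step_s
    if ecg.duration < w:
        log.warning("recording shorter than the %g s analysis window", w)
        return []
    sigma = _noise_sd(ecg)
    # pass 1: flag windows on R-R irregularity alone
    flagged = []
    t0 = 0.0
    while t0 + w <= ecg.duration + 1e-9:
        in_win = (beats.r_times >= t0) & (beats.r_times < t0 + w)
        r_win = beats.r_times[in_win]
        if r_win.size >= 4:
            rr = np.diff(r_win) * 1000.0
            cv = float(np.std(rr, ddof=1) / np.mean(rr))
            if cv > criteria.rr_cv_threshold:
                flagged.append((t0, t0 + w))
        t0 += step
    # merge overlapping flagged windows into candidate regions
    regions = []
    for start, end in flagged:
        if regions and start <= regions[-1][1] + 1e-9:
            regions[-1][1] = max(regions[-1][1], end)
        else:
            regions.append([start, end])
    # pass 2: a region is AF only when its beats carry no consistent pre-QRS
    # P deflection (beat-aligned median inside the noise band); pooling the
    # whole region's beats makes the median cancel random fibrillatory waves
    episodes = []
    for start, end in regions:
        in_reg = (beats.r_times >= start) & (beats.r_times < end)
        p_amp = _median_p_amplitude(ecg, beats.r_times[in_reg], criteria.p_window_ms)
        if p_amp < criteria.p_band_k * max(sigma, 1e-6):
            # a window flags when AF covers most of it, so the region support
            # overshoots the true episode by ~w/2 per side; trim to the
            # window centers for an unbiased boundary estimate
            s2, e2 = start + w / 2.0, end - w / 2.0
            if e2 > s2:
                episodes.append((s2, e2))
    qualifying = [(s, e) for s, e in episodes if e - s > criteria.min_episode_s]
    log.info("detect_af_episodes: %d flagged windows -> %d qualifying episodes",
             len(flagged), len(qualifying))
    return qualifying


def label_af_beats(beats: BeatTable, episodes: list) -> BeatTable:
    """Return a copy with beats inside any episode labeled in_AF."""
    labels = beats.labels.copy()
    for s, e in episodes:
        labels[(beats.r_times >= s) & (beats.r_times < e)] = IN_AF
    return BeatTable(r_times=beats.r_times.copy(), labels=labels)


def classify_animal_day(episode_lists: list, criteria: AFCriteria | None = None) -> bool:
    """True iff at least ``min_recordings_same_day`` of the day's recordings
    contain one or more qualifying episodes.  ``episode_lists`` is one episode
    list per same-day recording (as returned by ``detect_af_episodes``)."""
    criteria = criteria or AFCriteria()
    if not episode_lists:
        raise ConfigurationError("need >= 1 recording for an animal-day")
    n_with = sum(1 for eps in episode_lists if len(eps) > 0)
    return n_with >= criteria.min_recordings_same_day


def hrv_metrics(beats: BeatTable, window_s: float = 60.0) -> RhythmCall:
    """Heart-rate variability over the first ``window_s`` seconds.

    ``hr_sd`` is the SD of instantaneous heart rate in bpm (the headline
    measure); the SD of R-R in ms is reported alongside since either reading
    of "standard deviation of the heart rate" is in circulation.  Poincaré
    pairs (RR_n, RR_n+1) cover all consecutive intervals in the window.
    """
    sel = beats.r_times <= beats.r_times[0] + window_s if beats.n_beats else \
        np.zeros(0, dtype=bool)
    r = beats.r_times[sel]
    if r.size < 3:
        raise ConfigurationError("hrv_metrics needs >= 3 beats in the window")
    if beats.r_times[-1] - beats.r_times[0] < 0.9 * window_s:
        log.warning("hrv window shorter than %g s; computed on available span", window_s)
    rr = np.diff(r) * 1000.0
    hr = 60000.0 / rr
    pairs = np.column_stack([rr[:-1], rr[1:]]) if rr.size > 1 else np.empty((0, 2))
    return RhythmCall(
        episodes=[],
        hr_sd=float(np.std(hr, ddof=1)),
        rr_sd=float(np.std(rr, ddof=1)),
        poincare_pairs=pairs,
    )
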
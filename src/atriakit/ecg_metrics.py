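"""Beat detection and signal-averaged interval measurement for murine ECG.

The R detector is a differentiated-energy detector (band-pass, differentiate,
square, smooth) with a locally adaptive threshold and a 20 ms refractory
floor — the murine ventricular refractory period bounds any credible R-R
below.  Interval measurement follows signal averaging of 10 consecutive
regular sinus beats: fiducials are placed where the averaged waveform leaves
a k·sd noise band estimated on the isoelectric TP segment, then refined by
extrapolating the local deflection slope back to the isoelectric line (the
raw threshold crossing alone would move with the noise level).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import maximum_filter1d, uniform_filter1d
from scipy.signal import butter, find_peaks, sosfiltfilt

from .errors import ConfigurationError, InsufficientSinusBeatsError
from .io import ECGRecording

log = logging.getLogger(__name__)

SINUS, PAC, IN_AF, UNCLASSIFIED = "sinus", "PAC", "in_AF", "unclassified"
RR_FLOOR_MS = 20.0


@dataclass
class BeatTable:
    """Detected R peaks with intervals and per-beat rhythm labels."""

    r_times: np.ndarray                # s, strictly increasing
    labels: np.ndarray                 # {sinus, PAC, in_AF, unclassified}

    def __post_init__(self) -> None:
        self.r_times = np.asarray(self.r_times, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.r_times.size and np.any(np.diff(self.r_times) <= RR_FLOOR_MS / 1000.0):
            raise ValueError("r_times must be strictly increasing with RR > 20 ms")

    @property
    def n_beats(self) -> int:
        return self.r_times.size

    @property
    def rr_intervals(self) -> np.ndarray:
        """ms, length n_beats − 1; interval i ends at beat i+1."""
        return np.diff(self.r_times) * 1000.0

    @property
    def instantaneous_hr(self) -> np.ndarray:
        """bpm per R-R interval."""
        return 60000.0 / self.rr_intervals


@dataclass
class SignalAveragedBeat:
    waveform: np.ndarray               # mV
    sampling_rate: float               # Hz
    pre_samples: int                   # samples before the R sample
    n_beats_averaged: int
    fiducials: dict = field(default_factory=dict)   # ms relative to R

    @property
    def time_ms(self) -> np.ndarray:
        return (np.arange(self.waveform.size) - self.pre_samples) / self.sampling_rate * 1000.0


@dataclass
class EcgIntervals:
    p_duration: float                  # ms
    pr_interval: float                 # ms
    qrs_duration: float                # ms
    heart_rate: float                  # bpm
    n_tracings: int = 1
    flags: list = field(default_factory=list)


@dataclass
class FiducialConfig:
    noise_band_k: float = 2.0          # threshold in multiples of TP-segment sd
    qrs_search: float = 15.0           # ms either side of R
    p_search: float = 60.0             # ms before QRS onset
    min_run: float = 1.5               # ms a deflection must stay suprathreshold
    noise_fraction: float = 0.15       # leading fraction of the window used as TP
    fit_span: float = 2.0              # ms of slope used for edge extrapolation


# ---------------------------------------------------------------------------
# R-peak detection
# ---------------------------------------------------------------------------

def detect_r_peaks(ecg: ECGRecording) -> BeatTable:
    """Differentiated-energy QRS detector; returns all R times labeled sinus.

    A flat or saturated trace yields an empty table with a logged warning.
    """
    if ecg.sampling_rate < 1000:
        raise ConfigurationError("detect_r_peaks requires sampling_rate >= 1000 Hz")
    v = ecg.samples
    fs = ecg.sampling_rate
    if np.ptp(v) < 1e-9:
        log.warning("flat or saturated ECG signal; no beats detected")
        return BeatTable(r_times=np.empty(0), labels=np.empty(0, dtype=object))

    sos = butter(2, [10.0, min(300.0, 0.45 * fs)], btype="bandpass", fs=fs, output="sos")
    bp = sosfiltfilt(sos, v)
    energy = uniform_filter1d(np.diff(bp, prepend=bp[0]) ** 2,
                              size=max(3, int(round(0.008 * fs))))
    local_max = maximum_filter1d(energy, size=int(round(2.0 * fs)))
    height = 0.25 * np.maximum(local_max, 0.05 * energy.max())
    refractory = int(round(RR_FLOOR_MS / 1000.0 * fs))
    peaks, _ = find_peaks(energy, height=height, distance=refractory)

    # refine each detection to the raw R apex within +/-10 ms
    half = int(round(0.010 * fs))
    base = np.median(v)
    refined = []
    for p in peaks:
        lo, hi = max(p - half, 0), min(p + half + 1, v.size)
        refined.append(lo + int(np.argmax(np.abs(v[lo:hi] - base))))
    refined = np.unique(refined)
    if refined.size > 1:                # enforce the refractory floor post refine
        keep = [refined[0]]
        for idx in refined[1:]:
            if idx - keep[-1] >= refractory:
                keep.append(idx)
            elif abs(v[idx] - base) > abs(v[keep[-1]] - base):
                keep[-1] = idx
        refined = np.asarray(keep)
    r_times = refined / fs
    log.info("detect_r_peaks: %d beats in %.1f s", r_times.size, ecg.duration)
    return BeatTable(r_times=r_times, labels=np.full(r_times.size, SINUS, dtype=object))


# ---------------------------------------------------------------------------
# signal averaging
# ---------------------------------------------------------------------------

def _qualifying_runs(beats: BeatTable, n: int, rr_tolerance: float = 0.10):
    """Start indices of runs of n consecutive sinus beats with RR within
    ±rr_tolerance of the run median."""
    starts = []
    rr = beats.rr_intervals
    for s in range(beats.n_beats - n + 1):
        labs = beats.labels[s:s + n]
        if not np.all(labs == SINUS):
            continue
        seg = rr[s:s + n - 1]
        med = np.median(seg)
        if np.all(np.abs(seg - med) <= rr_tolerance * med):
            starts.append(s)
    return starts


def signal_average(ecg: ECGRecording, beats: BeatTable, n: int = 10,
                   start_beat: int | None = None) -> SignalAveragedBeat:
    """R-aligned mean of n consecutive regular sinus beats over
    [−0.6·RR, +0.4·RR] around each R peak."""
    if start_beat is None:
        runs = _qualifying_runs(beats, n)
        if not runs:
            raise InsufficientSinusBeatsError(
                f"no run of {n} consecutive regular sinus beats")
        start_beat = runs[0]
    fs = ecg.sampling_rate
    idx = np.round(beats.r_times[start_beat:start_beat + n] * fs).astype(int)
    rr_med = np.median(np.diff(beats.r_times[start_beat:start_beat + n])) if n > 1 \
        else np.median(np.diff(beats.r_times))
    pre = int(round(0.6 * rr_med * fs))
    post = int(round(0.4 * rr_med * fs))
    segs = []
    for i in idx:
        if i - pre < 0 or i + post >= ecg.samples.size:
            continue
        segs.append(ecg.samples[i - pre:i + post + 1])
    if len(segs) < n:
        raise InsufficientSinusBeatsError("qualifying beats fall outside the recording")
    return SignalAveragedBeat(
        waveform=np.mean(segs, axis=0),
        sampling_rate=fs,
        pre_samples=pre,
        n_beats_averaged=len(segs),
    )


# ---------------------------------------------------------------------------
# fiducials and intervals
# ---------------------------------------------------------------------------

def _edge_time(t: np.ndarray, y: np.ndarray, i_cross: int, into: int,
               fit_samples: int) -> float:
    """Extrapolate the deflection edge at suprathreshold sample ``i_cross``
    back to the isoelectric line, using a least-squares slope over
    ``fit_samples`` samples taken in direction ``into`` (towards the peak)."""
    sel = [i_cross + into * k for k in range(fit_samples + 1)]
    sel = [i for i in sel if 0 <= i < y.size]
    ts, ys = t[sel], y[sel]
    if len(sel) < 2 or np.ptp(ys) < 1e-15:
        return float(t[i_cross])
    slope, intercept = np.polyfit(ts, ys, 1)
    if abs(slope) < 1e-12:
        return float(t[i_cross])
    t0 = -intercept / slope
    # keep the extrapolation local: the true edge is at most the band width /
    # slope (a few ms) outside the crossing sample
    if into > 0:       # onset: the edge starts at or before the crossing
        return float(np.clip(t0, t[i_cross] - 5.0, t[i_cross]))
    return float(np.clip(t0, t[i_cross], t[i_cross] + 5.0))


def _deflection_runs(mask: np.ndarray):
    """(start, stop) index pairs of True runs; stop is inclusive."""
    padded = np.diff(np.concatenate([[0], mask.astype(int), [0]]))
    starts = np.nonzero(padded == 1)[0]
    stops = np.nonzero(padded == -1)[0] - 1
    return list(zip(starts, stops))


def measure_intervals(sab: SignalAveragedBeat,
                      config: FiducialConfig | None = None) -> EcgIntervals:
    """P duration, PR and QRS from one signal-averaged beat.

    Baseline and noise sd come from the leading (TP) segment of the window;
    onsets/offsets are k·sd band crossings refined by slope extrapolation.
    A missing P deflection (AF, sinus arrest) yields NaN with a flag.
    """
    config = config or FiducialConfig()
    fs = sab.sampling_rate
    t = sab.time_ms
    n_noise = max(int(config.noise_fraction * sab.waveform.size), 4)
    baseline = float(np.median(sab.waveform[:n_noise]))
    sigma = float(np.std(sab.waveform[:n_noise]))
    thr = max(config.noise_band_k * sigma, 1e-6)
    y = np.abs(sab.waveform - baseline)
    fit_n = max(int(round(config.fit_span / 1000.0 * fs)), 2)
    flags: list[str] = []

    # --- QRS: walk outward from the R apex until the signal re-enters the band
    r_idx = sab.pre_samples
    lo = np.searchsorted(t, -config.qrs_search)
    hi = np.searchsorted(t, config.qrs_search, side="right")
    i = r_idx
    while i > lo and y[i - 1] > thr:
        i -= 1
    qrs_on = _edge_time(t, y, i, +1, fit_n) if y[i] > thr or i < r_idx else t[i]
    j = r_idx
    while j < hi - 1 and y[j + 1] > thr:
        j += 1
    qrs_off = _edge_time(t, y, j, -1, fit_n) if y[j] > thr or j > r_idx else t[j]

    # --- P: first/last suprathreshold run inside the search window before QRS
    p_lo = np.searchsorted(t, qrs_on - config.p_search)
    p_hi = np.searchsorted(t, qrs_on - 1.0, side="right")
    window = y[p_lo:p_hi]
    min_run = max(int(round(config.min_run / 1000.0 * fs)), 1)
    runs = [(a + p_lo, b + p_lo) for a, b in _deflection_runs(window > thr)
            if (b - a + 1) >= min_run and window[a:b + 1].max() >= 1.5 * thr]
    if not runs:
        flags.append("no_p_deflection")
        p_on = p_off = np.nan
    else:
        p_on = _edge_time(t, y, runs[0][0], +1, fit_n)
        p_off = _edge_time(t, y, runs[-1][1], -1, fit_n)

    sab.fiducials = {"P_onset": p_on, "P_offset": p_off,
                     "QRS_onset": qrs_on, "QRS_offset": qrs_off}
    return EcgIntervals(
        p_duration=p_off - p_on,
        pr_interval=qrs_on - p_on,
        qrs_duration=qrs_off - qrs_on,
        heart_rate=np.nan,
        n_tracings=1,
        flags=flags,
    )


def measure_recording(ecg: ECGRecording, beats: BeatTable | None = None,
                      n_beats: int = 10, max_tracings: int = 50,
                      config: FiducialConfig | None = None) -> EcgIntervals:
    """Per-recording intervals: the mean over up to ``max_tracings`` sliding
    10-beat signal-averaged tracings (the per-animal quantification scheme).

    Fewer than ``max_tracings`` qualifying windows is reported with a quality
    flag, not an error.
    """
    if beats is None:
        beats = detect_r_peaks(ecg)
    runs = _qualifying_runs(beats, n_beats)
    if not runs:
        raise InsufficientSinusBeatsError("no qualifying 10-beat sinus run")
    take = runs[:max_tracings] if len(runs) >= max_tracings else runs
    measured = []
    for s in take:
        sab = signal_average(ecg, beats, n=n_beats, start_beat=s)
        measured.append(measure_intervals(sab, config))
    flags = sorted({f for m in measured for f in m.flags})
    if len(take) < max_tracings:
        flags.append(f"only_{len(take)}_tracings")
    sinus_rr = beats.rr_intervals[np.asarray(
        [beats.labels[k + 1] == SINUS for k in range(beats.n_beats - 1)])]
    hr = float(np.mean(60000.0 / sinus_rr)) if sinus_rr.size else np.nan
    with np.errstate(invalid="ignore"):
        return EcgIntervals(
            p_duration=float(np.nanmean([m.p_duration for m in measured])),
            pr_interval=float(np.nanmean([m.pr_interval for m in measured])),
            qrs_duration=float(np.nanmean([m.qrs_duration for m in measured])),
            heart_rate=hr,
            n_tracings=len(take),
            flags=flags,
        )


# ---------------------------------------------------------------------------
# premature atrial complexes
# ---------------------------------------------------------------------------

def detect_pac(beats: BeatTable, early_fraction: float = 0.80,
               history: int = 5) -> BeatTable:
    """Label premature beats: beat i is a PAC when its R-R is shorter than
    ``early_fraction`` x the median of the previous ``history`` sinus
    intervals and the beat is not inside an AF episode (AF labels, applied
    beforehand, take precedence).  Returns a relabeled copy."""
    if beats.n_beats < 6:
        raise ConfigurationError("detect_pac needs >= 6 beats")
    labels = beats.labels.copy()
    rr = beats.rr_intervals
    recent: list[float] = []
    for i in range(1, beats.n_beats):
        interval = rr[i - 1]
        if labels[i] == IN_AF or labels[i - 1] == IN_AF:
            continue
        if len(recent) >= history and interval < early_fraction * np.median(recent[-history:]):
            labels[i] = PAC
        elif labels[i] in (SINUS, UNCLASSIFIED):
            labels[i] = SINUS
            recent.append(interval)
    return BeatTable(r_times=beats.r_times.copy(), labels=labels)
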
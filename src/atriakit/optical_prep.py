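"""From raw voltage-dye movie to one normalized beat per pixel.

Processing chain, in fixed order: segment the recording into pacing-cycle
windows, ensemble-average the first 8 complete beats, spatially smooth each
frame with a 5x5 uniform kernel (reflect padding, NaN/ROI aware), then invert
(if the dye darkens on depolarization), baseline-subtract and peak-normalize
each pixel.  Pixels whose peak-to-baseline amplitude does not clear 5x the
diastolic noise floor are pruned from the ROI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter
from scipy.signal import find_peaks

from .errors import ConfigurationError, InsufficientBeatsError, NoSignalError
from .io import VoltageMovie
from .presets import POLARITY_DECREASES

log = logging.getLogger(__name__)


@dataclass
class EnsembleConfig:
    n_beats_to_average: int = 8
    smoothing_kernel: int = 5          # odd, pixels
    baseline_window: float = 10.0      # ms of diastole used for baseline/noise
    edge_mode: str = "reflect"

    def __post_init__(self) -> None:
        if self.n_beats_to_average < 1:
            raise ConfigurationError("n_beats_to_average must be >= 1")
        if self.smoothing_kernel < 1 or self.smoothing_kernel % 2 == 0:
            raise ConfigurationError("smoothing_kernel must be odd and >= 1")
        if self.baseline_window <= 0:
            raise ConfigurationError("baseline_window must be > 0")
        if self.edge_mode != "reflect":
            raise ConfigurationError("only reflect edge padding is supported")


@dataclass
class NormalizedBeat:
    """One ensemble-averaged, smoothed, normalized beat cycle per pixel.

    ``traces`` is (time, rows, cols), dimensionless in [0, 1] within the ROI
    (peak exactly 1 per pixel) and NaN outside it.
    """

    traces: np.ndarray
    frame_interval: float              # ms
    stimulus_offset: float             # ms from window start to the stimulus
    roi: np.ndarray                    # bool, post amplitude pruning
    amplitude_map: np.ndarray          # counts, peak minus baseline per pixel

    @property
    def n_samples(self) -> int:
        return self.traces.shape[0]

    @property
    def cycle_length(self) -> float:
        return self.n_samples * self.frame_interval


def _detect_stimuli(movie: VoltageMovie) -> np.ndarray:
    """Estimate stimulus times from the global mean trace when none are given."""
    mean = movie.frames.reshape(movie.n_frames, -1).mean(axis=1)
    if movie.polarity == POLARITY_DECREASES:
        mean = -mean
    dmean = np.diff(mean)
    if dmean.max() <= 0:
        raise InsufficientBeatsError("no periodic deflections detectable in mean trace")
    peaks, _ = find_peaks(dmean, height=0.5 * dmean.max(),
                          distance=max(2, int(10 / movie.frame_interval)))
    if peaks.size < 3:
        raise InsufficientBeatsError("need >= 3 detectable periodic deflections")
    return peaks * movie.frame_interval


def segment_beats(movie: VoltageMovie, config: EnsembleConfig | None = None) -> np.ndarray:
    """Return start indices of complete pacing-cycle windows, one per stimulus.

    The cycle length is the median inter-stimulus interval; each window starts
    at the stimulus sample and must fit entirely inside the recording.
    """
    config = config or EnsembleConfig()
    stim = movie.stimulus_times
    if stim.size == 0:
        stim = _detect_stimuli(movie)
    if stim.size < 2:
        raise InsufficientBeatsError("need >= 2 stimuli to define a cycle length")
    dt = movie.frame_interval
    cycle = float(np.median(np.diff(stim)))
    win_len = int(round(cycle / dt))
    starts = np.round(stim / dt).astype(int)
    starts = starts[starts + win_len <= movie.n_frames]
    if starts.size < config.n_beats_to_average:
        raise InsufficientBeatsError(
            f"only {starts.size} complete beats; need {config.n_beats_to_average}")
    log.info("segment_beats: %d complete windows of %d frames", starts.size, win_len)
    return np.stack([starts, starts + win_len], axis=1)


def ensemble_average(movie: VoltageMovie, windows: np.ndarray,
                     config: EnsembleConfig | None = None) -> np.ndarray:
    """Pointwise mean over the first ``n_beats_to_average`` windows (consecutive
    beats); returns a float stack one cycle long."""
    config = config or EnsembleConfig()
    n = config.n_beats_to_average
    if len(windows) < n:
        raise InsufficientBeatsError(f"only {len(windows)} windows; need {n}")
    lengths = {int(b - a) for a, b in windows[:n]}
    if len(lengths) != 1:
        raise RuntimeError("ragged beat windows")  # segment_beats guarantees equal
    stack = np.zeros((lengths.pop(),) + movie.frames.shape[1:], dtype=np.float64)
    for a, b in windows[:n]:
        stack += movie.frames[a:b].astype(np.float64)
    return stack / n


def spatial_smooth(stack: np.ndarray, roi: np.ndarray,
                   config: EnsembleConfig | None = None) -> np.ndarray:
    """Per-frame uniform-mean filter, reflect padded, averaging only in-ROI
    (and finite) neighbors.  Out-of-ROI pixels stay NaN."""
    config = config or EnsembleConfig()
    k = config.smoothing_kernel
    if k > min(stack.shape[1:]):
        raise ConfigurationError("smoothing kernel larger than the frame")
    if k == 1:
        out = stack.astype(np.float64).copy()
        out[:, ~roi] = np.nan
        return out
    valid = roi & np.isfinite(stack).all(axis=0)
    data = np.where(valid[None, :, :], stack, 0.0).astype(np.float64)
    num = uniform_filter(data, size=(1, k, k), mode="reflect")
    den = uniform_filter(valid.astype(np.float64), size=(k, k), mode="reflect")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den[None, :, :]
    out[:, ~roi] = np.nan
    return out


def normalize_invert(stack: np.ndarray, polarity: str, roi: np.ndarray,
                     frame_interval: float,
                     config: EnsembleConfig | None = None) -> NormalizedBeat:
    """Invert (dark-on-depolarization dyes), baseline-subtract and normalize.

    The baseline is the mean over the last ``baseline_window`` ms of the cycle
    — under steady-state pacing this is the diastolic segment immediately
    preceding the next stimulus.  Pixels with peak-to-baseline amplitude below
    5x the baseline noise s.d. (or with no amplitude at all) are pruned.
    """
    config = config or EnsembleConfig()
    n_t = stack.shape[0]
    n_base = int(round(config.baseline_window / frame_interval))
    if not 1 <= n_base < n_t:
        raise ConfigurationError("baseline_window does not fit inside the cycle")

    sig = -stack if polarity == POLARITY_DECREASES else stack.copy()
    base_seg = sig[n_t - n_base:]
    baseline = base_seg.mean(axis=0)
    noise_sd = base_seg.std(axis=0, ddof=1) if n_base > 1 else np.zeros_like(baseline)
    sig = sig - baseline[None]
    amplitude = np.nanmax(sig, axis=0) if np.isnan(sig).any() else sig.max(axis=0)

    keep = roi & np.isfinite(amplitude) & (amplitude > np.maximum(5.0 * noise_sd, 1e-9))
    if not keep.any():
        raise NoSignalError("no pixels survive amplitude-based ROI pruning")
    n_dropped = int(roi.sum() - keep.sum())
    if n_dropped:
        log.info("normalize_invert: dropped %d low-amplitude pixels from ROI", n_dropped)

    with np.errstate(invalid="ignore", divide="ignore"):
        traces = sig / amplitude[None]
    traces[:, ~keep] = np.nan
    amplitude = np.where(keep, amplitude, np.nan)
    return NormalizedBeat(
        traces=traces,
        frame_interval=frame_interval,
        stimulus_offset=0.0,
        roi=keep,
        amplitude_map=amplitude,
    )


def prepare_beat(movie: VoltageMovie, config: EnsembleConfig | None = None) -> NormalizedBeat:
    """Full chain: segment -> ensemble average -> spatial smooth -> normalize."""
    config = config or EnsembleConfig()
    windows = segment_beats(movie, config)
    stack = ensemble_average(movie, windows, config)
    stack = spatial_smooth(stack, movie.roi, config)
    return normalize_invert(stack, movie.polarity, movie.roi, movie.frame_interval, config)
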
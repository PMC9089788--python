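"""Activation, upstroke-velocity and APD maps from a normalized beat.

Conventions (standard in optical mapping):

* the activation instant of a pixel is the time of maximum dV/dt of its
  normalized trace, refined to sub-frame precision by fitting a parabola
  through the discrete derivative maximum and its neighbours;
* the upstroke velocity is the maximum rate of rise of the normalized (0-1)
  trace in 1/ms — absolute fluorescence units are arbitrary, so slopes are
  only meaningful after per-pixel normalization (the pre-normalization
  amplitude map is kept for anyone needing counts/ms);
* APD at repolarization level L (default 0.75) is the time from the
  activation instant to the first downward crossing of normalized amplitude
  1−L after the peak, with linear interpolation between samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import NoSignalError
from .optical_prep import NormalizedBeat


@dataclass
class ActivationMap:
    t_act: np.ndarray                  # ms from window start, NaN outside ROI
    activation_span: float             # ms
    span_method: str = "percentile"    # percentile (5th-95th) | minmax
    quality: dict = field(default_factory=dict)


@dataclass
class APDMap:
    apd: np.ndarray                    # ms, NaN outside ROI or unrecovered
    level: float = 0.75
    quality: dict = field(default_factory=dict)


@dataclass
class MapSummary:
    mean_apd75: float
    activation_span: float
    mean_max_slope: float
    n_roi_pixels: int
    region_label: str = "custom"


def _forward_derivative(beat: NormalizedBeat):
    """Forward differences of every ROI trace; (n_t-1, pixels) plus midpoint times."""
    dt = beat.frame_interval
    tr = beat.traces.reshape(beat.n_samples, -1)
    d = np.diff(tr, axis=0) / dt
    t_mid = (np.arange(d.shape[0]) + 0.5) * dt
    return tr, d, t_mid


def _refine_peak_time(d: np.ndarray, j: np.ndarray, dt: float) -> np.ndarray:
    """Quadratic sub-frame refinement of derivative-maximum times (ms)."""
    m = d.shape[0]
    t = (j + 0.5) * dt
    inner = (j >= 1) & (j <= m - 2)
    ji = j[inner]
    cols = np.nonzero(inner)[0]
    y0 = d[ji - 1, cols]
    y1 = d[ji, cols]
    y2 = d[ji + 1, cols]
    denom = y0 - 2.0 * y1 + y2
    offset = np.zeros_like(y1)
    ok = denom < -1e-12
    offset[ok] = 0.5 * (y0[ok] - y2[ok]) / denom[ok]
    offset = np.clip(offset, -0.5, 0.5)
    t[inner] = (ji + 0.5 + offset) * dt
    return t


def activation_map(beat: NormalizedBeat, span_method: str = "percentile") -> ActivationMap:
    """Per-pixel activation time plus a scalar span summary.

    The span is the 5th-95th percentile spread of in-ROI activation times
    (robust to single-pixel noise); ``span_method='minmax'`` gives the full
    max−min spread instead.  Pixels whose derivative maximum sits at the very
    end of the window (no real upstroke) are set NaN and counted.
    """
    tr, d, _ = _forward_derivative(beat)
    shape = beat.traces.shape[1:]
    t_act = np.full(tr.shape[1], np.nan)
    roi_flat = beat.roi.ravel()
    cols = np.nonzero(roi_flat)[0]
    if cols.size == 0:
        raise NoSignalError("empty ROI")
    ds = d[:, cols]
    j = np.argmax(ds, axis=0)
    t = _refine_peak_time(ds, j, beat.frame_interval)
    bad = j == ds.shape[0] - 1          # derivative max at the window end
    t[bad] = np.nan
    t_act[cols] = t
    finite = t_act[np.isfinite(t_act)]
    if finite.size == 0:
        raise NoSignalError("no pixel produced a usable activation time")
    if span_method == "minmax":
        span = float(finite.max() - finite.min())
    else:
        span = float(np.percentile(finite, 95) - np.percentile(finite, 5))
    return ActivationMap(
        t_act=t_act.reshape(shape),
        activation_span=span,
        span_method=span_method,
        quality={"n_edge_rejected": int(bad.sum()), "n_roi": int(cols.size)},
    )


def upstroke_velocity_map(beat: NormalizedBeat):
    """Per-pixel maximum upstroke slope (1/ms) and its ROI mean.

    The slope value is the raw maximum forward difference — refinement is
    applied to the *time* of the maximum (see ``activation_map``), not its
    value, so a linear ramp's slope and the one-frame sampling cap are
    reported exactly.
    """
    _, d, _ = _forward_derivative(beat)
    shape = beat.traces.shape[1:]
    slope = np.full(d.shape[1], np.nan)
    roi_flat = beat.roi.ravel()
    cols = np.nonzero(roi_flat)[0]
    if cols.size == 0:
        raise NoSignalError("empty ROI")
    slope[cols] = np.max(d[:, cols], axis=0)
    slope = slope.reshape(shape)
    return slope, float(np.nanmean(slope))


def apd_map(beat: NormalizedBeat, level: float = 0.75) -> APDMap:
    """Action potential duration at repolarization fraction ``level``.

    APD = (first downward crossing of 1−level after the peak, linearly
    interpolated) − (activation time).  Traces that never recover below the
    threshold within the cycle are NaN and flagged.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    act = activation_map(beat)
    dt = beat.frame_interval
    tr = beat.traces.reshape(beat.n_samples, -1)
    cols = np.nonzero(beat.roi.ravel())[0]
    thr = 1.0 - level

    sub = tr[:, cols]
    peak = np.argmax(sub, axis=0)
    idx = np.arange(sub.shape[0])[:, None]
    below = (sub < thr) & (idx > peak[None, :])
    has_cross = below.any(axis=0)
    first = np.argmax(below, axis=0)

    apd_flat = np.full(tr.shape[1], np.nan)
    t_act = act.t_act.ravel()[cols]
    ccols = np.nonzero(has_cross)[0]
    j = first[ccols] - 1
    v0 = sub[j, ccols]
    v1 = sub[j + 1, ccols]
    frac = (v0 - thr) / (v0 - v1)
    t_cross = (j + frac) * dt
    vals = t_cross - t_act[ccols]
    apd_flat[cols[ccols]] = vals
    apd_flat[apd_flat <= 0] = np.nan
    return APDMap(
        apd=apd_flat.reshape(beat.traces.shape[1:]),
        level=level,
        quality={"n_no_recovery": int((~has_cross).sum()), "n_roi": int(cols.size)},
    )


def roi_summary(beat: NormalizedBeat, region_label: str = "custom",
                region: np.ndarray | None = None, level: float = 0.75) -> MapSummary:
    """Arithmetic means over the finite pixels of all three maps.

    ``region`` optionally restricts the summary to a sub-mask (e.g. the left
    atrium within a field that also images ventricle).
    """
    if region is not None:
        beat = NormalizedBeat(
            traces=np.where(region[None], beat.traces, np.nan),
            frame_interval=beat.frame_interval,
            stimulus_offset=beat.stimulus_offset,
            roi=beat.roi & region,
            amplitude_map=beat.amplitude_map,
        )
    if not beat.roi.any():
        raise NoSignalError("empty ROI for region summary")
    act = activation_map(beat)
    apd = apd_map(beat, level=level)
    _, mean_slope = upstroke_velocity_map(beat)
    return MapSummary(
        mean_apd75=float(np.nanmean(apd.apd)),
        activation_span=act.activation_span,
        mean_max_slope=mean_slope,
        n_roi_pixels=int(beat.roi.sum()),
        region_label=region_label,
    )


def isochrone_contours(act: ActivationMap, n_levels: int = 10, out_png=None):
    """Isochrone levels (ms) of an activation map; optionally render a PNG."""
    finite = act.t_act[np.isfinite(act.t_act)]
    if finite.size == 0:
        raise NoSignalError("activation map has no finite pixels")
    levels = np.linspace(finite.min(), finite.max(), n_levels + 2)[1:-1]
    if out_png is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 4))
        im = ax.imshow(act.t_act, cmap="viridis")
        ax.contour(act.t_act, levels=levels, colors="white", linewidths=0.7)
        fig.colorbar(im, ax=ax, label="activation time (ms)")
        ax.set_title("isochrones")
        fig.savefig(out_png, dpi=150)
        plt.close(fig)
    return levels
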
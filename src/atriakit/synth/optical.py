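"""Synthetic voltage-dye movies of a paced heart surface.

Each pixel carries an identical action-potential template time-shifted by a
propagating wavefront.  The template is a linear upstroke of duration
``upstroke_rise_time`` followed by a truncated-exponential repolarization
whose decay constant is solved so that the 75%-repolarization point falls
exactly ``apd75_true`` after the maximum-slope instant (the ramp midpoint).
The repolarization is pinned to zero a guard interval before the next
stimulus, so the diastolic baseline window used downstream is genuinely
isoelectric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from ..errors import ConfigurationError
from ..io import VoltageMovie
from ..presets import PLANAR, POLARITY_DECREASES, OpticalPreset

RECOVERY_LEVEL = 0.25      # normalized amplitude remaining at 75% repolarization


@dataclass
class OpticalGroundTruth:
    """Construction-time truth for one generated movie (per-pixel, ms units)."""

    activation_delay: np.ndarray   # ms from each stimulus to max-slope instant
    apd75: np.ndarray              # ms
    max_slope: np.ndarray          # 1/ms on the normalized (0-1) template
    stimulus_times: np.ndarray     # ms
    roi: np.ndarray                # bool mask

    def to_frame(self) -> pd.DataFrame:
        rows, cols = np.nonzero(np.ones_like(self.activation_delay, dtype=bool))
        return pd.DataFrame({
            "row": rows,
            "col": cols,
            "t_act_ms": self.activation_delay[rows, cols],
            "apd75_ms": self.apd75[rows, cols],
            "max_slope_per_ms": self.max_slope[rows, cols],
        })


def activation_delays(preset: OpticalPreset) -> np.ndarray:
    """Ground-truth conduction delay (ms) of every pixel from the stimulus.

    Planar geometry: the wavefront travels along the column axis away from the
    pacing-site column, so delay = |col − site_col| · pitch / velocity.  Point
    geometry uses the Euclidean distance to the pacing site (circular fronts).
    An infinite conduction velocity activates every pixel simultaneously.
    """
    rows, cols = preset.grid_size
    r0, c0 = preset.pacing_site
    rr, cc = np.mgrid[0:rows, 0:cols]
    if preset.wave_geometry == PLANAR:
        dist = np.abs(cc - c0) * preset.pixel_pitch
    else:
        dist = np.hypot(rr - r0, cc - c0) * preset.pixel_pitch
    return preset.stimulus_latency + dist / preset.conduction_velocity


def _solve_tau(crossing: float, span: float) -> float:
    """Decay constant of ``(e^{-x/tau} - E)/(1 - E)`` (E = e^{-span/tau}) such
    that the curve equals RECOVERY_LEVEL at x = crossing and 0 at x = span."""
    lvl = RECOVERY_LEVEL
    if not span > crossing > 0:
        raise ConfigurationError(
            "repolarization does not fit in the cycle: need "
            "pacing_cycle_length - baseline_guard > activation delay + apd75_true")

    def f(tau: float) -> float:
        return np.exp(-crossing / tau) - lvl - (1.0 - lvl) * np.exp(-span / tau)

    return brentq(f, 1e-3, 1e7, xtol=1e-12, rtol=1e-15)


def _template_matrix(preset: OpticalPreset, delays: np.ndarray, tt: np.ndarray) -> np.ndarray:
    """Normalized AP value for beat-relative times ``tt`` (n_t,) at every pixel.

    Returns an (n_t, n_pixels) array in [0, 1]; ``delays`` is flattened.
    """
    rise = preset.upstroke_rise_time
    cl = preset.pacing_cycle_length
    guard = preset.baseline_guard
    crossing = preset.apd75_true - rise / 2.0

    flat = delays.ravel()
    x = tt[:, None] - flat[None, :]          # time since max-slope instant
    u = np.zeros_like(x)

    ramp = (x >= -rise / 2.0) & (x < rise / 2.0)
    u[ramp] = (x[ramp] + rise / 2.0) / rise

    # per-pixel decay span; pixels sharing a delay share a decay constant
    spans = cl - guard - flat - rise / 2.0
    for d in np.unique(flat):
        sel = flat == d
        span = cl - guard - d - rise / 2.0
        tau = _solve_tau(crossing, span)
        e_end = np.exp(-span / tau)
        xs = x[:, sel]
        dec = (xs >= rise / 2.0) & (xs < rise / 2.0 + span)
        vals = (np.exp(-(xs[dec] - rise / 2.0) / tau) - e_end) / (1.0 - e_end)
        block = u[:, sel]
        block[dec] = vals
        u[:, sel] = block
    del spans
    return u


def generate_optical_movie(preset: OpticalPreset, seed: int):
    """Render a paced movie plus its ground truth.

    Returns ``(VoltageMovie, OpticalGroundTruth)``.  Identical preset and seed
    give bit-identical output; all randomness comes from ``seed``.
    """
    dt = preset.frame_interval
    cl = preset.pacing_cycle_length
    n_frames = int(round((preset.lead_in + preset.n_beats * cl) / dt))
    t = np.arange(n_frames) * dt
    stim = preset.lead_in + np.arange(preset.n_beats) * cl

    delays = activation_delays(preset)
    rows, cols = preset.grid_size
    u_total = np.zeros((n_frames, rows * cols))

    rise = preset.upstroke_rise_time
    for s in stim:
        lo = np.searchsorted(t, s - rise)           # template is 0 before -rise/2
        hi = np.searchsorted(t, s + cl, side="right")
        tt = t[lo:hi] - s
        u_total[lo:hi] += _template_matrix(preset, delays, tt)

    u_total = u_total.reshape(n_frames, rows, cols)
    sign = -1.0 if preset.polarity == POLARITY_DECREASES else 1.0
    frames = preset.baseline_level + sign * preset.ap_amplitude * u_total

    rng = np.random.default_rng(seed)
    if preset.noise_sd > 0:
        frames = frames + rng.normal(0.0, preset.noise_sd, frames.shape)
    frames = np.clip(np.round(frames), 0, np.iinfo(np.uint16).max).astype(np.uint16)

    roi = (np.ones((rows, cols), dtype=bool) if preset.roi is None
           else np.asarray(preset.roi, dtype=bool))
    movie = VoltageMovie(
        frames=frames,
        frame_interval=dt,
        pixel_pitch=preset.pixel_pitch,
        stimulus_times=stim,
        polarity=preset.polarity,
        roi=roi,
    )
    truth = OpticalGroundTruth(
        activation_delay=delays,
        apd75=np.full((rows, cols), preset.apd75_true),
        max_slope=np.full((rows, cols), 1.0 / rise),
        stimulus_times=stim,
        roi=roi,
    )
    return movie, truth
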
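"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pytest

from atriakit import presets
from atriakit.synth import generate_ecg, generate_optical_movie


@pytest.fixture(scope="session")
def small_optical_preset():
    """16x16 grid, 8 beats: fast enough for per-test regeneration."""
    return presets.con_optical(grid_size=(16, 16), pacing_site=(8, 0), n_beats=8)


@pytest.fixture(scope="session")
def con_movie_noiseless():
    movie, truth = generate_optical_movie(presets.con_optical(noise_sd=0.0), seed=0)
    return movie, truth


@pytest.fixture(scope="session")
def con_ecg_60s():
    ecg, truth = generate_ecg(presets.con_ecg(), 60.0, seed=7)
    return ecg, truth


def make_beat(traces, frame_interval=1.0, roi=None):
    """Wrap a (t, r, c) array as a NormalizedBeat for map-level fixtures."""
    from atriakit.optical_prep import NormalizedBeat

    traces = np.asarray(traces, dtype=float)
    if roi is None:
        roi = np.ones(traces.shape[1:], dtype=bool)
    amp = np.ones(traces.shape[1:])
    return NormalizedBeat(traces=traces, frame_interval=frame_interval,
                          stimulus_offset=0.0, roi=roi, amplitude_map=amp)
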
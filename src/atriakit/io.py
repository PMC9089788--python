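"""On-disk formats: voltage-dye movies, ECG traces, scalar maps, tables, masks.

Conventions
-----------
* Optical times are in ms, ECG times in s, all map values in ms.
* Pixel indices are 0-based, row-major, origin top-left.
* ``NaN`` is the only undefined-value sentinel (maps outside the ROI).
* Movies are multi-page 16-bit grayscale TIFF (page order = time) with a JSON
  sidecar; ECGs are two-column CSV (``time_s``, ``voltage_mV``) with a JSON
  sidecar; maps are written both as CSV grids and 32-bit float TIFF.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError
from .presets import POLARITY_DECREASES, POLARITY_INCREASES

log = logging.getLogger(__name__)

MOVIE_SIDECAR_KEYS = ("frame_interval_ms", "pixel_pitch_mm", "stimulus_times_ms", "polarity")
ECG_SIDECAR_KEYS = ("sampling_rate_hz", "lead")


@dataclass
class VoltageMovie:
    """A time-ordered stack of fluorescence frames with physical metadata."""

    frames: np.ndarray                 # (time, rows, cols) intensity counts
    frame_interval: float              # ms
    pixel_pitch: float                 # mm
    stimulus_times: np.ndarray         # ms, strictly increasing
    polarity: str
    roi: np.ndarray                    # (rows, cols) bool

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.stimulus_times = np.asarray(self.stimulus_times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise FormatError("frames: need a (time, rows, cols) stack with >= 2 frames")
        self.roi = np.asarray(self.roi).astype(bool)
        if self.roi.shape != self.frames.shape[1:]:
            raise FormatError("roi: mask shape does not match frame shape")
        if self.polarity not in (POLARITY_DECREASES, POLARITY_INCREASES):
            raise FormatError(f"polarity: unknown value {self.polarity!r}")
        t = self.stimulus_times
        if t.size and np.any(np.diff(t) <= 0):
            raise FormatError("stimulus_times_ms: must be strictly increasing")
        span = self.frames.shape[0] * self.frame_interval
        if t.size and (t[0] < 0 or t[-1] >= span):
            raise FormatError("stimulus_times_ms: outside the recording span")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration(self) -> float:
        """Recording span in ms."""
        return self.n_frames * self.frame_interval


@dataclass
class ECGRecording:
    """Uniformly sampled single-lead voltage trace in mV."""

    samples: np.ndarray
    sampling_rate: float               # Hz
    lead: str = "II"
    recording_id: str = ""
    animal_id: str = ""
    day: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise FormatError("samples: need a 1-D series with >= 2 samples")
        if self.sampling_rate <= 0:
            raise FormatError("sampling_rate_hz: must be > 0")

    @property
    def duration(self) -> float:
        """Seconds."""
        return self.samples.size / self.sampling_rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate


# ---------------------------------------------------------------------------
# movies
# ---------------------------------------------------------------------------

def write_movie(movie: VoltageMovie, tiff_path, sidecar_path, roi_path=None) -> None:
    tiff_path, sidecar_path = Path(tiff_path), Path(sidecar_path)
    frames = movie.frames
    if frames.dtype != np.uint16:
        frames = np.clip(np.round(frames), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(tiff_path, frames, photometric="minisblack")
    meta = {
        "frame_interval_ms": movie.frame_interval,
        "pixel_pitch_mm": movie.pixel_pitch,
        "stimulus_times_ms": list(map(float, movie.stimulus_times)),
        "polarity": movie.polarity,
    }
    if roi_path is not None:
        roi_path = Path(roi_path)
        write_mask(movie.roi, roi_path)
        meta["roi_mask_path"] = roi_path.name
    sidecar_path.write_text(json.dumps(meta, indent=1))


def read_movie(tiff_path, sidecar_path) -> VoltageMovie:
    tiff_path, sidecar_path = Path(tiff_path), Path(sidecar_path)
    if not tiff_path.exists():
        raise FormatError(f"movie file not found: {tiff_path}")
    if not sidecar_path.exists():
        raise FormatError(f"sidecar file not found: {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    for key in MOVIE_SIDECAR_KEYS:
        if key not in meta:
            raise FormatError(f"sidecar missing required key: {key}")
    frames = tifffile.imread(tiff_path)
    if frames.ndim == 2:
        frames = frames[None]
    if "roi_mask_path" in meta:
        roi = read_mask(sidecar_path.parent / meta["roi_mask_path"])
        if roi.shape != frames.shape[1:]:
            raise FormatError("roi_mask_path: mask shape does not match frame shape")
    else:
        log.warning("no ROI mask referenced by %s; using full-frame mask", sidecar_path)
        roi = np.ones(frames.shape[1:], dtype=bool)
    return VoltageMovie(
        frames=frames,
        frame_interval=float(meta["frame_interval_ms"]),
        pixel_pitch=float(meta["pixel_pitch_mm"]),
        stimulus_times=np.asarray(meta["stimulus_times_ms"], dtype=float),
        polarity=str(meta["polarity"]),
        roi=roi,
    )


# ---------------------------------------------------------------------------
# masks (8-bit PNG or TIFF; nonzero = inside ROI)
# ---------------------------------------------------------------------------

def write_mask(mask: np.ndarray, path) -> None:
    path = Path(path)
    img = (np.asarray(mask).astype(bool) * np.uint8(255))
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, img)
    else:
        iio.imwrite(path, img, extension=path.suffix or ".png")


def read_mask(path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"mask file not found: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        img = tifffile.imread(path)
    else:
        img = iio.imread(path)
    if img.ndim == 3:                  # collapse any colour channels
        img = img[..., 0]
    return img > 0


# ---------------------------------------------------------------------------
# ECG traces
# ---------------------------------------------------------------------------

def write_ecg(ecg: ECGRecording, csv_path, sidecar_path) -> None:
    csv_path, sidecar_path = Path(csv_path), Path(sidecar_path)
    df = pd.DataFrame({"time_s": ecg.time, "voltage_mV": ecg.samples})
    df.to_csv(csv_path, index=False, float_format="%.9f")
    meta = {
        "sampling_rate_hz": ecg.sampling_rate,
        "lead": ecg.lead,
        "recording_id": ecg.recording_id,
        "animal_id": ecg.animal_id,
        "day": ecg.day,
    }
    sidecar_path.write_text(json.dumps(meta, indent=1))


def read_ecg(csv_path, sidecar_path) -> ECGRecording:
    csv_path, sidecar_path = Path(csv_path), Path(sidecar_path)
    if not sidecar_path.exists():
        raise FormatError(f"sidecar file not found: {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    for key in ECG_SIDECAR_KEYS:
        if key not in meta:
            raise FormatError(f"sidecar missing required key: {key}")
    try:
        df = pd.read_csv(csv_path)
    except (pd.errors.EmptyDataError, FileNotFoundError) as exc:
        raise FormatError(f"ECG csv unreadable: {csv_path}: {exc}") from exc
    for col in ("time_s", "voltage_mV"):
        if col not in df.columns:
            raise FormatError(f"ECG csv missing column: {col}")
    if len(df) < 2:
        raise FormatError("ECG csv: need >= 2 samples")
    fs = float(meta["sampling_rate_hz"])
    t = df["time_s"].to_numpy(dtype=float)
    expected = np.arange(t.size) / fs + t[0]
    if np.max(np.abs(t - expected)) > 1e-6:
        raise FormatError("time_s: non-uniform sampling (tolerance 1e-6 s)")
    return ECGRecording(
        samples=df["voltage_mV"].to_numpy(dtype=float),
        sampling_rate=fs,
        lead=str(meta["lead"]),
        recording_id=str(meta.get("recording_id", "")),
        animal_id=str(meta.get("animal_id", "")),
        day=str(meta.get("day", "")),
    )


# ---------------------------------------------------------------------------
# scalar maps and flat tables
# ---------------------------------------------------------------------------

def write_map(map_values: np.ndarray, path) -> None:
    """Write a 2-D scalar map; ``path`` may end in .csv or .tif/.tiff.

    CSV encodes the grid row-by-row with NaN for undefined pixels; TIFF is a
    32-bit float image with NaN preserved.
    """
    path = Path(path)
    arr = np.asarray(map_values, dtype=np.float32)
    if arr.ndim != 2:
        raise FormatError("map must be 2-D")
    if path.suffix.lower() == ".csv":
        pd.DataFrame(arr).to_csv(path, index=False, header=False, float_format="%.6f")
    elif path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        raise FormatError(f"unsupported map extension: {path.suffix}")


def read_map(path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"map file not found: {path}")
    if path.suffix.lower() == ".csv":
        try:
            df = pd.read_csv(path, header=None)
        except pd.errors.EmptyDataError as exc:
            raise FormatError(f"empty map csv: {path}") from exc
        return df.to_numpy(dtype=np.float32)
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path).astype(np.float32)
    raise FormatError(f"unsupported map extension: {path.suffix}")


def write_table(rows, path) -> None:
    """Write a table (DataFrame or list of dicts) as a comma-separated CSV."""
    pd.DataFrame(rows).to_csv(Path(path), index=False)


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    try:
        return pd.read_csv(path)
    except (pd.errors.EmptyDataError, FileNotFoundError) as exc:
        raise FormatError(f"table unreadable: {path}: {exc}") from exc
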
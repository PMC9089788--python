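"""Generator presets for the control (CON) and atrial-AMPK-knockout (dKO) phenotypes.

Only the dKO/CON *ratios* are anchored to the published phenotype (conduction
slowing, upstroke depression, APD_75 prolongation, P-wave widening, PR
prolongation, heart-rate-variability increase, Pitx2c/Mef2c gradients).
Absolute control values are fixed generator choices drawn from murine
physiology; see docs/methods.md for each choice and its rationale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .errors import ConfigurationError

# Dye polarity conventions. di-4-ANEPPS fluorescence falls on depolarization,
# so raw optical traces are upside-down and need inversion downstream.
POLARITY_DECREASES = "fluorescence_decreases_on_depolarization"
POLARITY_INCREASES = "fluorescence_increases_on_depolarization"

PLANAR = "planar"
POINT = "point"


@dataclass
class OpticalPreset:
    """Parameters of one synthetic voltage-dye movie.

    Times are in ms, distances in mm, intensities in camera counts.
    ``conduction_velocity=math.inf`` is the simultaneous-activation flag
    (every pixel fires at the stimulus, useful for symmetry fixtures).
    """

    grid_size: tuple[int, int] = (80, 80)          # rows, cols
    pixel_pitch: float = 0.05                      # mm between pixel centres
    frame_interval: float = 1.0                    # ms per frame
    pacing_cycle_length: float = 100.0             # ms (10 Hz pacing)
    n_beats: int = 10
    conduction_velocity: float = 0.5               # mm/ms
    upstroke_rise_time: float = 2.0                # ms, linear-ramp duration
    apd75_true: float = 35.0                       # ms from max-slope instant
    ap_amplitude: float = 1000.0                   # counts, peak minus baseline
    baseline_level: float = 2000.0                 # counts, diastolic level
    noise_sd: float = 20.0                         # counts, i.i.d. Gaussian
    polarity: str = POLARITY_DECREASES
    pacing_site: tuple[int, int] = (40, 0)         # row, col of the electrode
    stimulus_latency: float = 2.0                  # ms, stimulus-to-capture delay
    wave_geometry: str = PLANAR                    # planar | point
    lead_in: float = 20.0                          # ms of baseline before stim 1
    baseline_guard: float = 12.0                   # ms of guaranteed diastole
                                                   # before each stimulus
    roi: object = None                             # None -> full frame, or a
                                                   # bool (rows, cols) array

    def __post_init__(self) -> None:
        dt = self.frame_interval
        if dt <= 0 or self.pacing_cycle_length <= 0:
            raise ConfigurationError("frame_interval and pacing_cycle_length must be > 0")
        n = self.pacing_cycle_length / dt
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError(
                "pacing_cycle_length must be an integer number of frame intervals")
        if self.pacing_cycle_length < self.apd75_true + self.baseline_guard:
            raise ConfigurationError(
                "pacing cycle too short: need cycle_length >= apd75_true + baseline_guard")
        if self.n_beats < 8:
            raise ConfigurationError("n_beats must be >= 8 (ensemble averaging needs 8)")
        if not self.conduction_velocity > 0:
            raise ConfigurationError("conduction_velocity must be > 0")
        if not (self.apd75_true > self.upstroke_rise_time > 0):
            raise ConfigurationError("need apd75_true > upstroke_rise_time > 0")
        if self.polarity not in (POLARITY_DECREASES, POLARITY_INCREASES):
            raise ConfigurationError(f"unknown polarity {self.polarity!r}")
        if self.wave_geometry not in (PLANAR, POINT):
            raise ConfigurationError(f"unknown wave_geometry {self.wave_geometry!r}")
        r, c = self.pacing_site
        rows, cols = self.grid_size
        if not (0 <= r < rows and 0 <= c < cols):
            raise ConfigurationError("pacing_site outside the grid")


@dataclass
class EcgPreset:
    """Parameters of one synthetic single-lead murine surface ECG.

    Intervals in ms, amplitudes in mV.  ``af_episodes`` is a list of
    (start_s, duration_s) intervals during which P waves are replaced by
    continuous fibrillatory oscillation and RR becomes irregular with
    coefficient of variation ``rr_irregularity``.
    """

    sampling_rate: float = 2000.0                  # Hz
    heart_rate: float = 500.0                      # bpm, sinus mean
    p_duration: float = 12.0                       # ms
    pr_interval: float = 38.0                      # ms, P onset -> QRS onset
    qrs_duration: float = 10.0                     # ms
    p_morphology: str = "single_peak"              # single_peak | double_peak
    pac_rate: float = 0.0                          # premature beats / min
    hr_sd_scale: float = 1.0                       # target HR-SD multiple of CON
    af_episodes: list[tuple[float, float]] = field(default_factory=list)
    rr_irregularity: float = 0.25                  # CV of RR during AF
    noise_sd: float = 0.01                         # mV
    # waveform shape choices (generator internals, all mV / ms)
    p_amplitude: float = 0.15
    qrs_amplitude: float = 1.0
    t_amplitude: float = 0.15
    t_width: float = 20.0
    t_gap: float = 4.0                             # ms between QRS end and T start
    fwave_amplitude: float = 0.04
    fwave_freq: float = 12.0                       # Hz
    rr_jitter: float = 2.0                         # ms, sinus RR s.d.
    pac_coupling: float = 0.6                      # PAC RR as fraction of mean RR
    af_rr_scale: float = 0.9                       # mean AF RR / sinus RR

    def __post_init__(self) -> None:
        if self.sampling_rate < 1000:
            raise ConfigurationError("sampling_rate must be >= 1000 Hz")
        for name in ("heart_rate", "p_duration", "pr_interval", "qrs_duration"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.pr_interval <= self.p_duration:
            raise ConfigurationError("pr_interval must exceed p_duration")
        if self.p_morphology not in ("single_peak", "double_peak"):
            raise ConfigurationError(f"unknown p_morphology {self.p_morphology!r}")
        for start, dur in self.af_episodes:
            if start < 0 or dur <= 0:
                raise ConfigurationError("af_episodes must have start >= 0 and duration > 0")


@dataclass
class QpcrPreset:
    """True per-group ΔCt values (target − reference) behind a synthetic Ct table.

    ``delta_ct`` maps (gene, group) to the true mean ΔCt.  Fold changes between
    groups are 2**(−ΔΔCt) of these, so preset fold ratios hold by construction.
    """

    delta_ct: dict[tuple[str, str], float]
    reference_gene: str = "Gapdh"
    reference_ct: float = 18.0
    noise_sd: float = 0.15                         # Ct s.d. per replicate

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not self.delta_ct:
            raise ConfigurationError("delta_ct table is empty")


# ---------------------------------------------------------------------------
# Built-in preset table.  dKO values are derived from CON by the published
# effect sizes, so the ground-truth ratios hold exactly by construction.
# ---------------------------------------------------------------------------

ACTIVATION_SLOWING = 1.4       # dKO activation time / CON (40% increase)
UPSTROKE_FACTOR = 0.5          # dKO max upstroke slope / CON (50% decrease)
APD75_PROLONGATION = 1.5       # dKO APD_75 / CON (~50% prolongation)
P_DURATION_FACTOR = 2.0        # dKO week-1 P duration / CON
PR_FACTOR = 1.10               # dKO week-1 PR / CON
QRS_FACTOR = 1.0               # ventricular activation unaffected
HR_SD_FACTOR = 3.0             # dKO week-2-4 HR standard deviation / CON
PITX2C_LA_RA_FOLD = 160.0      # CON left vs right atrium
PITX2C_DKO_FOLD = 0.40         # dKO LA vs CON LA (60% reduction)
MEF2C_LA_RA_FOLD = 1.75        # CON left vs right atrium


def con_optical(**overrides) -> OpticalPreset:
    return replace(OpticalPreset(), **overrides)


def dko_optical(**overrides) -> OpticalPreset:
    con = OpticalPreset()
    p = replace(
        con,
        conduction_velocity=con.conduction_velocity / ACTIVATION_SLOWING,
        upstroke_rise_time=con.upstroke_rise_time / UPSTROKE_FACTOR,
        apd75_true=con.apd75_true * APD75_PROLONGATION,
    )
    return replace(p, **overrides)


def con_ecg(**overrides) -> EcgPreset:
    return replace(EcgPreset(), **overrides)


def dko_ecg_wk1(**overrides) -> EcgPreset:
    con = EcgPreset()
    p = replace(
        con,
        p_duration=con.p_duration * P_DURATION_FACTOR,
        pr_interval=con.pr_interval * PR_FACTOR,
        qrs_duration=con.qrs_duration * QRS_FACTOR,
        p_morphology="double_peak",
    )
    return replace(p, **overrides)


def dko_ecg_wk2_4(**overrides) -> EcgPreset:
    p = replace(dko_ecg_wk1(), pac_rate=2.0, hr_sd_scale=HR_SD_FACTOR)
    return replace(p, **overrides)


def dko_ecg_af(**overrides) -> EcgPreset:
    """dKO with one established 40-s AF episode inside a 60-s recording."""
    p = replace(dko_ecg_wk2_4(), af_episodes=[(10.0, 40.0)])
    return replace(p, **overrides)


def qpcr_preset(**overrides) -> QpcrPreset:
    """Pitx2c and Mef2c ΔCt table for CON/dKO left and right atria.

    Right-atrial ΔCt anchors are arbitrary generator choices; the left-atrial
    values are offset by −log2(fold) so interatrial and genotype folds are
    exact.  dKO right atria are unchanged; the dKO Mef2c gradient is abolished
    (LA pulled down to the RA level).
    """
    pitx_ra = 10.0
    mef_ra = 6.0
    table = {
        ("Pitx2c", "CON_RA"): pitx_ra,
        ("Pitx2c", "CON_LA"): pitx_ra - math.log2(PITX2C_LA_RA_FOLD),
        ("Pitx2c", "dKO_RA"): pitx_ra,
        ("Pitx2c", "dKO_LA"): pitx_ra - math.log2(PITX2C_LA_RA_FOLD)
        - math.log2(PITX2C_DKO_FOLD),
        ("Mef2c", "CON_RA"): mef_ra,
        ("Mef2c", "CON_LA"): mef_ra - math.log2(MEF2C_LA_RA_FOLD),
        ("Mef2c", "dKO_RA"): mef_ra,
        ("Mef2c", "dKO_LA"): mef_ra,
    }
    return replace(QpcrPreset(delta_ct=table), **overrides)


OPTICAL_PRESETS = {"CON_optical": con_optical, "dKO_optical": dko_optical}
ECG_PRESETS = {
    "CON_ecg": con_ecg,
    "dKO_ecg_wk1": dko_ecg_wk1,
    "dKO_ecg_wk2_4": dko_ecg_wk2_4,
    "dKO_ecg_af": dko_ecg_af,
}
QPCR_PRESETS = {"qpcr": qpcr_preset}
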
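# Methods

This note documents the models behind the synthetic-data generator, the
measurement conventions of the analysis pipelines, the defaults that matter,
and the design decisions taken where the underlying experimental procedure is
underdetermined.

## 1. Synthetic optical movies

Each pixel of the 80×80 field (50 µm pitch) carries the same normalized
action-potential template, time-shifted by a propagating wavefront and scaled
to camera counts.

**Wavefront.** Default geometry is a planar front travelling along the column
axis away from the pacing-site column: conduction delay = |col − col₀| ·
pitch / velocity. A point-source mode (Euclidean distance, circular
isochrones) exists for radial fixtures. A `stimulus_latency` (default 2 ms)
models the electrode capture delay and, practically, keeps the earliest
upstroke fully inside the stimulus-aligned analysis window; setting the
conduction velocity to `inf` activates the whole field simultaneously.
Ground-truth activation per pixel is latency + delay; spans and group ratios
are independent of the latency.

**Template.** A linear upstroke of duration `upstroke_rise_time` (max-slope
instant = ramp midpoint = the ground-truth activation time) rises to the peak,
followed by a truncated-exponential repolarization
v(x) = (e^(−x/τ) − E)/(1 − E), E = e^(−S/τ), pinned to exactly zero at the
end of its span S (one `baseline_guard` = 12 ms before the next stimulus, so
the diastolic baseline window is genuinely isoelectric). The decay constant τ
is solved per conduction delay (Brent's method, |f| < 1e−12) so the
75%-repolarization level is crossed exactly `apd75_true` after the max-slope
instant — the APD₇₅ truth is a construction, not a fit. Pixels sharing a
delay share a τ.

**Counts and noise.** Fluorescence = baseline − amplitude·v (the default
polarity models dyes that darken on depolarization, so downstream inversion
is required; polarity is recorded in the sidecar, never assumed), plus i.i.d.
Gaussian noise, rounded to 16-bit counts. Defaults: baseline 2000, amplitude
1000, noise SD 20 counts (SNR 50 — a good rodent preparation). All
randomness flows from the single integer seed; identical preset + seed is
bit-identical.

**Presets.** Control: velocity 0.5 mm/ms (crosses the 4-mm field in ~8 ms),
rise 2 ms, APD₇₅ 35 ms, 10 beats at cycle length 100 ms, 1 ms frames (the
camera rate is configurable; 1 kHz is typical for rodent mapping CCDs).
Knockout: velocity /1.4, rise ×2 (half the upstroke slope), APD₇₅ ×1.5.
Only these ratios are phenotype-anchored; the absolute control values are
generator choices from murine physiology and are never tuned.

## 2. Optical processing chain

Fixed order: segment → ensemble average → spatial smooth → normalize.

* **Segmentation**: one window per stimulus, starting at the stimulus sample,
  one cycle long (median inter-stimulus interval), complete windows only.
  Without stimulus annotations, upstrokes of the global mean trace serve as
  surrogates (≥3 periodic deflections required).
* **Ensemble average**: pointwise mean of the *first* 8 complete beats
  ("8 consecutive" read literally; deterministic).
* **Spatial smoothing**: per-frame 5×5 uniform kernel, reflect padding
  (avoids amplitude bias at tissue edges), NaN/ROI-aware (only in-ROI
  neighbours are averaged).
* **Normalization**: per pixel — invert if the dye darkens, baseline = mean
  of the last 10 ms of the cycle (under steady-state pacing this is the
  diastole immediately before the next stimulus), amplitude = peak −
  baseline, trace = (signal − baseline)/amplitude. Per-pixel (not per-field)
  normalization is required for level-crossing APD thresholds to be
  meaningful pixelwise. Pixels with amplitude below 5× the baseline-window
  noise SD (or with no amplitude at all) are pruned from the ROI and counted.

## 3. Maps

* **Activation** = time of maximum temporal derivative. Forward differences
  (midpoint-timed) locate the maximum; a parabola through the maximum and its
  neighbours refines the time below the 1-ms frame interval (a 2-ms upstroke
  is only ~2 frames). A derivative maximum at the window end marks a
  non-physiological trace: NaN plus a quality count.
* **Upstroke velocity** reports the *raw* maximum forward difference on the
  normalized trace (1/ms). Quadratic refinement is deliberately not applied
  to the value: it inflates flat-topped derivative profiles (a linear ramp
  would read 0.5625/ms instead of 0.5), and a sub-frame rise should read
  exactly the sampling-capped 1/Δt. Absolute fluorescence units are
  arbitrary, hence slopes on normalized amplitude; the pre-normalization
  amplitude map is preserved for anyone needing counts/ms.
* **APD at level L** (default 0.75) = first downward crossing of 1−L after
  the peak (linear interpolation between samples) minus the activation time.
  Traces that never recover below the threshold within the cycle are NaN and
  flagged.
* **Activation span** = 5th–95th percentile spread of in-ROI activation
  times — robust to single-pixel noise; max−min is available via
  `span_method="minmax"` and is what the noiseless planar-wave oracle uses
  (the 5×5 reflect-padded kernel pulls edge columns inward by ~0.1 ms, a bias
  that is proportional to the conduction delay and therefore cancels exactly
  in group ratios).
* **Summaries** are arithmetic means over finite pixels, optionally within a
  region sub-mask (e.g. left atrium vs ventricle in one field).

On noiseless generated movies the chain recovers per-pixel activation and
APD₇₅ within one frame interval for ≥99% of ROI pixels (tested), the main
residuals being sampling of the true peak and kernel mixing.

## 4. Synthetic ECG

Beats are deflection templates at 2 kHz: a triangular QRS (10 ms, 1 mV), a
triangular P wave (12 ms, 0.15 mV; the double-peaked variant is two
overlapping humps spanning exactly the preset duration — the fragmented-P
morphology of atrial conduction delay), and a raised-cosine T (20 ms,
0.15 mV) placed clear of the next P window. PR (P onset → QRS onset) is 38 ms
in controls; the knockout presets double P and prolong PR by 10% with QRS
unchanged. Sinus R-R is 120 ms (500 bpm) with 2-ms Gaussian jitter. The
piecewise-linear edges make the fiducial ground truth exact.

**Ectopy.** PACs are inserted as early beats at 60% of the mean cycle, at
`pac_rate` per minute (default 2 in the week-2–4 preset). Because the preset
demands a fixed heart-rate-variability multiple (3× control), the post-PAC
pause is solved numerically on the realized R-R sequence so the 60-s SD of
instantaneous HR equals `hr_sd_scale` × the delta-method sinus value
(60000·σ_RR/RR₀²) exactly; the multiple is thus a construction, not an
emergent average.

**Atrial fibrillation.** Within an episode, P waves disappear, R-R is drawn
with coefficient of variation 0.25 (mean 0.9× sinus), and a
frequency-wandering ~12-Hz oscillation of 0.04 mV models fibrillatory waves.
The ground truth records beat labels, fiducials, the episode intervals and a
per-sample AF mask.

## 5. ECG measurement

* **R detection**: band-pass (10–300 Hz, zero-phase), differentiate, square,
  8-ms smoothing; locally adaptive threshold (25% of the 2-s rolling
  envelope maximum) with a 20-ms refractory floor; detections are refined to
  the raw R apex. Flat traces yield an empty table with a warning.
* **Signal averaging**: the mean of 10 consecutive sinus beats whose R-R lie
  within ±10% of the run median, over [−0.6·RR, +0.4·RR] around R. Per
  recording, up to 50 sliding qualifying windows are measured and averaged
  ("at least 50 tracings"); fewer windows is a quality flag, not an error.
* **Fiducials**: noise SD σ from the leading TP segment of the averaged
  window; onsets/offsets where |waveform − baseline| leaves the 2σ band
  (suprathreshold runs ≥1.5 ms, peak ≥3σ, to ignore noise blips), refined by
  a least-squares slope over the following 2 ms extrapolated back to the
  isoelectric line. The refinement removes the threshold rule's
  noise-dependent bias: without it, measured durations shrink by
  ~2·σ/slope, violating noiseless recovery at the ±1 ms level. A missing P
  deflection reports NaN with a flag (AF, sinus arrest).
* **PAC rule**: beat *i* is premature when RR_i < 0.80 × median of the
  previous 5 sinus intervals; beats inside detected AF episodes are labeled
  `in_AF` first and take precedence.

## 6. AF classification and HRV

"Disorganized atrial activity with irregularly conducted QRS" is
operationalized as two conditions: (a) R-R coefficient of variation > 0.15
within sliding 5-s windows (step 1 s), and (b) no consistent pre-QRS P
deflection. Condition (b) is evaluated on merged CV-flagged regions rather
than single windows: the pointwise median of beat-aligned pre-QRS segments
([−50, −8] ms relative to R) cancels random fibrillatory waves over hundreds
of beats but preserves a repeating P wave, and is compared against 2× a
robust noise estimate (scaled MAD of the differenced trace). Flagged regions
overshoot the true episode by about half a window per side (a window flags
when mostly covered), so boundaries are trimmed by w/2 before the duration
rule — episodes must exceed 30 s — is applied. The thresholds (CV 0.15, 5-s
window, k = 2) are calibrated, configurable artifact decisions, not claims
about the original instrumentation. The animal-day diagnosis is positive iff
≥2 same-day recordings contain a qualifying episode.

HRV reports the SD of instantaneous heart rate (bpm) over the first 60 s —
with the SD of R-R (ms) alongside, since "standard deviation of the heart
rate" admits either reading — plus all consecutive (RR_n, RR_{n+1}) Poincaré
pairs (n beats → n−2 pairs).

## 7. qPCR and statistics

The Ct generator assigns each replicate a reference-gene Ct (Gapdh, 18.0)
and target Cts offset by the preset's true ΔCt, each with independent
Gaussian noise (default 0.15 Ct), so expected folds equal the preset exactly
and the noiseless table is exact: interatrial Pitx2c ΔCt = −log₂160, the
knockout left atrium +log₂2.5 above the control left atrium, Mef2c gradient
−log₂1.75 abolished in the knockout. Fold changes use the standard
ΔΔCt = mean ΔCt(group A) − mean ΔCt(group B), fold = 2^(−ΔΔCt). Group
statistics are deliberately plain: two-tailed Student's *t* (mean ± SEM,
n ≥ 2 enforced; two degenerate identical groups report t = 0, p = 1), and
two-way ANOVA with Holm–Šidák-adjusted pairwise comparisons for factorial
designs.

## 8. Problem sizes and limitations

Validation and the acceptance script run at desk scale: 5 movies per group
(80×80 × ~1 s at 1 kHz), 5–10 one-minute ECGs per group, 100 recordings per
arm for classifier specificity/sensitivity. These sizes give group-mean
ratios stable to a few percent while keeping the whole suite in minutes.

What the generator does **not** model — and hence what passing tests do not
demonstrate about real data: motion artifact (experiments use an
electromechanical uncoupler, so none is simulated), fluorescence
photobleaching and drift beyond a constant baseline, spatially heterogeneous
conduction or repolarization, curved or re-entrant wavefronts, multi-lead
ECG projection, T-P overlap at very high heart rates, atrial flutter, and
biophysical ionic dynamics (no Hodgkin–Huxley/monodomain solver — templates
are kinematic). The classifiers and fiducial rules are therefore validated
for their stated operational definitions, not as clinical-grade detectors.
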
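"""Signal-averaged ECG intervals: P duration, PR, QRS, heart rate.

Generates 60-s control and early-knockout surface ECGs, detects R peaks,
averages 10-beat sinus tracings (50 sliding tracings per recording) and
measures fiducial-based intervals.  The knockout preset encodes P-wave
doubling and a 10% PR prolongation with unchanged QRS.
"""

from atriakit import presets
from atriakit.ecg_metrics import detect_r_peaks, measure_recording
from atriakit.synth import generate_ecg

rows = {}
for name, factory in (("CON", presets.con_ecg), ("dKO wk1", presets.dko_ecg_wk1)):
    ecg, truth = generate_ecg(factory(), 60.0, seed=2)
    res = measure_recording(ecg, detect_r_peaks(ecg))
    rows[name] = res
    print(f"{name:8s}: P {res.p_duration:5.2f} ms | PR {res.pr_interval:5.2f} ms | "
          f"QRS {res.qrs_duration:5.2f} ms | HR {res.heart_rate:5.0f} bpm "
          f"({res.n_tracings} tracings)")

con, dko = rows["CON"], rows["dKO wk1"]
print(f"\nratios dKO/CON: P {dko.p_duration / con.p_duration:.2f}, "
      f"PR {dko.pr_interval / con.pr_interval:.2f}, "
      f"QRS {dko.qrs_duration / con.qrs_duration:.2f}")
print("P doubling with a modest PR change and stable QRS is the atrial "
      "conduction-delay signature: the deletion is atrium-selective.")
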
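"""Optical action-potential mapping: activation, upstroke and APD_75 maps.

Generates one control and one knockout-phenotype voltage-dye movie (80x80
pixels, 10 paced beats at 10 Hz), runs the processing chain (8-beat ensemble
average, 5x5 spatial smoothing, baseline subtraction, inversion,
normalization) and prints the left-atrial map summaries side by side.
"""

import numpy as np

from atriakit import presets
from atriakit.optical_maps import activation_map, apd_map, roi_summary, \
    upstroke_velocity_map
from atriakit.optical_prep import prepare_beat
from atriakit.synth import generate_optical_movie

summaries = {}
for name, factory in (("CON", presets.con_optical), ("dKO", presets.dko_optical)):
    movie, truth = generate_optical_movie(factory(), seed=1)
    beat = prepare_beat(movie)
    s = roi_summary(beat, region_label="LA")
    summaries[name] = s
    print(f"{name}: activation span {s.activation_span:5.2f} ms | "
          f"mean upstroke {s.mean_max_slope:.3f} /ms | "
          f"mean APD75 {s.mean_apd75:5.2f} ms  ({s.n_roi_pixels} pixels)")

con, dko = summaries["CON"], summaries["dKO"]
print(f"\ndKO/CON ratios: activation {dko.activation_span / con.activation_span:.2f} "
      f"(conduction slowing), upstroke {dko.mean_max_slope / con.mean_max_slope:.2f} "
      f"(depolarization depression), APD75 {dko.mean_apd75 / con.mean_apd75:.2f} "
      f"(repolarization prolongation)")
print("A ratio of 1.4 / 0.5 / 1.5 reproduces the knockout atrial phenotype "
      "encoded in the presets.")
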
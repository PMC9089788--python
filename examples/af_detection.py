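"""Atrial-fibrillation episode detection and the per-day diagnosis rule.

Simulates an animal-day of two 1-minute recordings carrying a 40-s AF episode
each plus one clean recording, detects episodes (R-R irregularity with no
consistent P deflection, episodes must exceed 30 s) and applies the rule:
AF-positive iff at least two same-day recordings contain an episode.
"""

from atriakit import presets
from atriakit.ecg_metrics import detect_r_peaks
from atriakit.rhythm import classify_animal_day, detect_af_episodes
from atriakit.synth import generate_ecg

episode_lists = []
for i, factory in enumerate([presets.dko_ecg_af, presets.dko_ecg_af,
                             presets.con_ecg]):
    ecg, truth = generate_ecg(factory(), 60.0, seed=10 + i)
    eps = detect_af_episodes(ecg, detect_r_peaks(ecg))
    episode_lists.append(eps)
    shown = ", ".join(f"{s:.1f}-{e:.1f} s" for s, e in eps) or "none"
    true = ", ".join(f"{s:.0f}-{e:.0f} s" for s, e in truth.af_episodes) or "none"
    print(f"recording {i + 1}: episodes {shown} (ground truth {true})")

print(f"\nanimal-day AF diagnosis: {classify_animal_day(episode_lists)}")
print("Two recordings with >30 s episodes on the same day satisfy the "
      "diagnosis rule; sub-30-s irregularity would not.")
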
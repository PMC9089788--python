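"""ΔΔCt fold changes: the interatrial Pitx2c gradient and its loss.

Generates a replicate Ct table from the preset ΔCt truth (reference gene
Gapdh) and computes 2^(−ΔΔCt) folds for the comparisons of interest, plus a
two-group t test on the per-sample ΔCt values.
"""

from atriakit import presets
from atriakit.stats_report import compare_groups, fold_change
from atriakit.synth import generate_ct_table

table = generate_ct_table(presets.qpcr_preset(), n_replicates=6, seed=5)

for label, target, a, b in [
    ("Pitx2c LA vs RA (CON)", "Pitx2c", "CON_LA", "CON_RA"),
    ("Pitx2c dKO-LA vs CON-LA", "Pitx2c", "dKO_LA", "CON_LA"),
    ("Mef2c  LA vs RA (CON)", "Mef2c", "CON_LA", "CON_RA"),
]:
    fc = fold_change(table, target, "Gapdh", a, b)
    print(f"{label:26s}: fold {fc.fold:7.2f}  (ddCt {fc.ddct:+.3f}, "
          f"n={fc.n_a}/{fc.n_b})")

wide = table.pivot_table(index=["group", "sample"], columns="gene", values="ct")
dct = wide["Pitx2c"] - wide["Gapdh"]
res = compare_groups(dct.loc["dKO_LA"], dct.loc["CON_LA"], "dKO vs CON LA dCt")
print(f"\nΔCt t test (dKO vs CON left atria): t = {res.statistic:.2f}, "
      f"p = {res.p_value:.2g}")
print("A ~160-fold left-right gradient in controls and a ~0.4-fold knockout "
      "reduction reproduce the preset (noise makes folds approximate).")
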
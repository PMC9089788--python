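"""Synthetic RT-qPCR Ct tables with exact expected fold changes.

Each biological replicate gets a reference-gene Ct and target-gene Cts offset
by the preset's true ΔCt, each with independent Gaussian replicate noise, so
the expected 2^(−ΔΔCt) between any two groups equals the preset fold change
and the noiseless table reproduces it exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..errors import ConfigurationError
from ..presets import QpcrPreset


def generate_ct_table(preset: QpcrPreset, n_replicates: int, seed: int) -> pd.DataFrame:
    """Long-format table with columns ``sample``, ``group``, ``gene``, ``ct``."""
    if n_replicates < 2:
        raise ConfigurationError("n_replicates must be >= 2")
    rng = np.random.default_rng(seed)
    groups = sorted({g for (_, g) in preset.delta_ct})
    genes = sorted({t for (t, _) in preset.delta_ct})
    rows = []
    for group in groups:
        for rep in range(n_replicates):
            sample = f"{group}_{rep + 1}"
            ref_ct = preset.reference_ct + rng.normal(0.0, preset.noise_sd)
            rows.append({"sample": sample, "group": group,
                         "gene": preset.reference_gene, "ct": ref_ct})
            for gene in genes:
                if (gene, group) not in preset.delta_ct:
                    continue
                ct = (preset.reference_ct + preset.delta_ct[(gene, group)]
                      + rng.normal(0.0, preset.noise_sd))
                rows.append({"sample": sample, "group": group, "gene": gene, "ct": ct})
    return pd.DataFrame(rows)
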
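"""Group-comparison statistics and ΔΔCt fold-change arithmetic.

These are reporting plumbing, not bespoke inference: two-tailed Student's
t tests for two-group designs, two-way ANOVA with Holm–Šidák-adjusted
pairwise comparisons for factorial designs, and the standard relative-qPCR
quantification fold = 2^(−ΔΔCt).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError

log = logging.getLogger(__name__)


@dataclass
class GroupResult:
    mean_a: float
    sem_a: float
    n_a: int
    mean_b: float
    sem_b: float
    n_b: int
    test: str
    statistic: float
    p_value: float
    comparison: str = ""


@dataclass
class FoldChange:
    target: str
    reference: str
    ddct: float
    fold: float
    n_a: int = 0
    n_b: int = 0


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(len(x)))


def compare_groups(values_a, values_b, comparison: str = "") -> GroupResult:
    """Two-tailed Student's t test between two groups with mean ± SEM.

    Two identical degenerate groups (zero variance, equal means) report
    t = 0, p = 1 rather than an undefined statistic.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ConfigurationError("compare_groups needs n >= 2 per group")
    if np.std(a) == 0 and np.std(b) == 0:
        if np.mean(a) == np.mean(b):
            t, p = 0.0, 1.0
        else:
            t, p = np.inf * np.sign(np.mean(a) - np.mean(b)), 0.0
    else:
        t, p = stats.ttest_ind(a, b)
    return GroupResult(
        mean_a=float(np.mean(a)), sem_a=_sem(a), n_a=len(a),
        mean_b=float(np.mean(b)), sem_b=_sem(b), n_b=len(b),
        test="two-tailed Student's t", statistic=float(t), p_value=float(p),
        comparison=comparison,
    )


def holm_sidak(p_values) -> np.ndarray:
    """Holm–Šidák-adjusted p values (identity for a single comparison)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm-sidak")[1]


def two_way_anova(data: pd.DataFrame, value: str, factor_a: str, factor_b: str):
    """Two-way ANOVA with interaction plus Holm–Šidák-adjusted pairwise t tests
    of factor_a within each level of factor_b.

    Returns ``(anova_table, pairwise_frame)``.
    """
    for col in (value, factor_a, factor_b):
        if col not in data.columns:
            raise ConfigurationError(f"column missing from design: {col}")
    if data.groupby([factor_a, factor_b])[value].count().min() < 2:
        raise ConfigurationError("two_way_anova needs n >= 2 per cell")
    model = ols(f"Q('{value}') ~ C(Q('{factor_a}')) * C(Q('{factor_b}'))", data=data).fit()
    table = anova_lm(model, typ=2)
    rows = []
    for level, sub in data.groupby(factor_b):
        levels_a = sorted(sub[factor_a].unique())
        if len(levels_a) != 2:
            continue
        res = compare_groups(
            sub.loc[sub[factor_a] == levels_a[0], value],
            sub.loc[sub[factor_a] == levels_a[1], value],
            comparison=f"{levels_a[0]} vs {levels_a[1]} @ {factor_b}={level}",
        )
        rows.append({"comparison": res.comparison, "t": res.statistic,
                     "p_raw": res.p_value})
    pairwise = pd.DataFrame(rows)
    if len(pairwise):
        pairwise["p_holm_sidak"] = holm_sidak(pairwise["p_raw"].to_numpy())
    return table, pairwise


def fold_change(ct_table: pd.DataFrame, target: str, reference: str,
                group_a: str, group_b: str) -> FoldChange:
    """Relative quantification: ΔCt = Ct_target − Ct_reference per sample,
    ΔΔCt = mean ΔCt(group_a) − mean ΔCt(group_b), fold = 2^(−ΔΔCt).

    ``group_a`` is the condition of interest, ``group_b`` the calibrator.
    """
    for col in ("sample", "group", "gene", "ct"):
        if col not in ct_table.columns:
            raise ConfigurationError(f"ct table missing column: {col}")
    wide = ct_table.pivot_table(index=["group", "sample"], columns="gene",
                                values="ct", aggfunc="mean")
    for gene in (target, reference):
        if gene not in wide.columns:
            raise ConfigurationError(f"gene missing from ct table: {gene}")
    dct = (wide[target] - wide[reference]).dropna()
    groups = dct.index.get_level_values("group")
    a = dct[groups == group_a]
    b = dct[groups == group_b]
    if a.empty or b.empty:
        raise ConfigurationError(
            f"group missing from ct table: {group_a if a.empty else group_b}")
    ddct = float(a.mean() - b.mean())
    return FoldChange(target=target, reference=reference, ddct=ddct,
                      fold=float(2.0 ** (-ddct)), n_a=len(a), n_b=len(b))


def write_manifest(out_dir, inputs: dict, config: dict, seed=None) -> Path:
    """Reproducibility manifest written next to every CLI output."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "package": "atriakit",
        "version": __version__,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "config": config,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": seed,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, default=str))
    return path
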
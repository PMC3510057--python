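"""Phenotype endpoints: kidney/body-weight ratio, cystic index, and
two-group comparison with a Student-t confidence interval."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import pooled_t


def kidney_ratio(kw1: float, kw2: float, bw: float) -> float:
    """Combined kidney weight over twice the body weight: (kw1+kw2)/(2*bw)."""
    if min(kw1, kw2, bw) <= 0:
        raise ValueError("weights must be positive")
    return (kw1 + kw2) / (2.0 * bw)


def cystic_index(cystic_area: float, total_area: float) -> float:
    """Fraction of the kidney section occupied by cysts."""
    if total_area <= 0:
        raise ValueError("total area must be positive")
    if cystic_area < 0 or cystic_area > total_area:
        raise ValueError("cystic area must lie in [0, total area]")
    return cystic_area / total_area


@dataclass(frozen=True)
class GroupDifference:
    difference: float
    ci_low: float
    ci_high: float
    p: float
    n_a: int
    n_b: int


def group_difference(values_a, values_b, welch: bool = False) -> GroupDifference:
    """Two-group mean difference with 95% CI and two-sided p.

    Pooled-variance Student t by default (Welch by flag); the CI is
    difference +- t_{0.975, df} * se.  Zero pooled variance with equal
    means yields p = 1 and a degenerate [0, 0] interval.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per group")
    diff = float(a.mean() - b.mean())
    if welch:
        res = stats.ttest_ind(a, b, equal_var=False)
        t, p = float(res.statistic), float(res.pvalue)
        df = float(res.df)
        se = abs(diff / t) if t != 0 else np.nan
    else:
        t, p, df = pooled_t(a, b)
        sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
        se = float(np.sqrt(sp2 * (1.0 / a.size + 1.0 / b.size)))
    if se == 0.0 or not np.isfinite(se):
        if diff == 0.0:
            return GroupDifference(0.0, 0.0, 0.0, 1.0, a.size, b.size)
        return GroupDifference(diff, diff, diff, 0.0, a.size, b.size)
    crit = float(stats.t.ppf(0.975, df))
    return GroupDifference(diff, diff - crit * se, diff + crit * se, p, a.size, b.size)


def phenotype_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-animal endpoints and genotype comparison from a phenotype table.

    Expects columns genotype, body_weight, kidney_weight_1, kidney_weight_2,
    cystic_area, total_area.  Animals missing a kidney weight are excluded
    with a warning.  Returns a summary row per endpoint (kidney_ratio,
    cystic_index) with group means, difference (mutant - control), 95% CI
    and p.
    """
    tab = table.copy()
    missing = tab[["kidney_weight_1", "kidney_weight_2", "body_weight"]].isna().any(axis=1)
    if missing.any():
        warnings.warn(f"excluding {int(missing.sum())} animals with missing weights")
        tab = tab[~missing]
    tab["kidney_ratio"] = [
        kidney_ratio(r.kidney_weight_1, r.kidney_weight_2, r.body_weight)
        for r in tab.itertuples()
    ]
    tab["cystic_index"] = [
        cystic_index(r.cystic_area, r.total_area) for r in tab.itertuples()
    ]
    rows = []
    for endpoint in ("kidney_ratio", "cystic_index"):
        mut = tab.loc[tab["genotype"] == "mutant", endpoint].to_numpy()
        ctrl = tab.loc[tab["genotype"] == "control", endpoint].to_numpy()
        d = group_difference(mut, ctrl)
        rows.append(
            {
                "endpoint": endpoint,
                "n_mutant": d.n_a,
                "n_control": d.n_b,
                "mean_mutant": float(mut.mean()),
                "mean_control": float(ctrl.mean()),
                "difference": d.difference,
                "ci_low": d.ci_low,
                "ci_high": d.ci_high,
                "p": d.p,
            }
        )
    return pd.DataFrame(rows).set_index("endpoint")
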
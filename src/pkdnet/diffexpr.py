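"""Stratified two-group differential expression and the mutant-signature rule.

Within each age stratum, mutant vs control is tested per gene with a
pooled-variance two-sample t statistic (the two-level one-way ANOVA F is
its square), p-values are BH-adjusted across genes within the stratum, and
fold changes are reported on the anti-logged scale.  The mutant signature
is the gene set showing some evidence of differential expression at P12
(|fc| above threshold OR q below threshold) and fulfilling both criteria
at P14.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, SampleMetadata


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min over j >= i of m * p_(j) / j, capped at 1; input order
    preserved.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, int]:
    """Pooled-variance two-sample t statistic, two-sided p, df.

    Degenerate zero-variance cases: equal means -> (0, 1); unequal means ->
    p = 0 with a warning (the difference is certain at machine precision).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("need >= 2 observations per group")
    df = na + nb - 2
    diff = a.mean() - b.mean()
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    if sp2 == 0.0:
        if diff == 0.0:
            return 0.0, 1.0, df
        warnings.warn("zero pooled variance with unequal means; p set to 0")
        return np.inf if diff > 0 else -np.inf, 0.0, df
    t = diff / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(min(p, 1.0)), df


def signed_fold_change(log2fc: np.ndarray) -> np.ndarray:
    """Signed fold change: |fc| = 2^|log2fc|, sign(fc) = sign(log2fc).

    A log2 difference of 0 maps to fc = 1 (no change); the magnitude is
    always >= 1, matching the intensity-ratio convention.
    """
    log2fc = np.asarray(log2fc, float)
    mag = np.exp2(np.abs(log2fc))
    return np.where(log2fc < 0, -mag, mag)


def two_group_test(
    x: ExpressionMatrix, meta: SampleMetadata, stratum: str
) -> pd.DataFrame:
    """Per-gene mutant vs control test within one age stratum.

    Returns a DataFrame indexed by gene id with columns stratum, mean_mut,
    mean_ctrl, log2fc, fc, p, q.
    """
    meta = meta.aligned_to(x)
    in_stratum = meta.table["age"] == stratum
    if not in_stratum.any():
        raise ValueError(f"stratum {stratum!r} has no samples")
    mut = meta.samples_where(age=stratum, genotype="mutant")
    ctrl = meta.samples_where(age=stratum, genotype="control")
    if len(mut) < 2 or len(ctrl) < 2:
        raise ValueError(f"stratum {stratum!r} needs >= 2 samples per genotype")

    vm = x.values[mut].to_numpy(float)
    vc = x.values[ctrl].to_numpy(float)
    na, nb = vm.shape[1], vc.shape[1]
    df = na + nb - 2
    mean_mut = vm.mean(axis=1)
    mean_ctrl = vc.mean(axis=1)
    diff = mean_mut - mean_ctrl
    sp2 = ((na - 1) * vm.var(axis=1, ddof=1) + (nb - 1) * vc.var(axis=1, ddof=1)) / df
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = se == 0.0
    if degenerate.any():
        zero_diff = degenerate & (diff == 0.0)
        p[zero_diff] = 1.0
        if (degenerate & ~zero_diff).any():
            warnings.warn("zero pooled variance with unequal means; p set to 0")
            p[degenerate & ~zero_diff] = 0.0
    p = np.minimum(p, 1.0)
    return pd.DataFrame(
        {
            "stratum": stratum,
            "mean_mut": mean_mut,
            "mean_ctrl": mean_ctrl,
            "log2fc": diff,
            "fc": signed_fold_change(diff),
            "p": p,
            "q": bh_fdr(p),
        },
        index=x.values.index.rename("gene_id"),
    )


@dataclass(frozen=True)
class SignatureThresholds:
    fc: float = 1.2
    q: float = 0.05


def derive_signature(
    de12: pd.DataFrame,
    de14: pd.DataFrame,
    fc_thresh: float = 1.2,
    q_thresh: float = 0.05,
) -> pd.DataFrame:
    """Mutant-signature rule across the two age strata.

    A gene enters the signature when it shows some evidence at P12 (|fc| >
    fc_thresh OR q < q_thresh) and fulfils both criteria at P14.
    """
    if set(de12.index) != set(de14.index):
        only12 = sorted(set(de12.index) - set(de14.index))[:5]
        only14 = sorted(set(de14.index) - set(de12.index))[:5]
        raise ValueError(
            f"gene sets differ between strata (P12-only e.g. {only12}, "
            f"P14-only e.g. {only14})"
        )
    de14 = de14.loc[de12.index]
    out = pd.DataFrame(index=de12.index.rename("gene_id"))
    out["p12_pass_fc"] = de12["fc"].abs() > fc_thresh
    out["p12_pass_q"] = de12["q"] < q_thresh
    out["p14_pass_fc"] = de14["fc"].abs() > fc_thresh
    out["p14_pass_q"] = de14["q"] < q_thresh
    out["in_signature"] = (out["p12_pass_fc"] | out["p12_pass_q"]) & (
        out["p14_pass_fc"] & out["p14_pass_q"]
    )
    return out


def collapse_probes(
    results: pd.DataFrame,
    probe2gene: dict[str, str],
    p_col: str = "p",
    rule: str = "min_p",
) -> pd.DataFrame:
    """Collapse probe-level rows to genes.

    Default rule keeps, per gene, the probe with the smallest p-value in
    ``p_col`` (intended: the P14 test); ``rule='max_mean'`` keeps the probe
    with the highest mean expression instead.  The chosen probe id is
    recorded.
    """
    unmapped = [pr for pr in results.index if pr not in probe2gene]
    if unmapped:
        raise ValueError(f"unmapped probes: {unmapped[:5]}")
    if rule not in ("min_p", "max_mean"):
        raise ValueError(f"unknown collapse rule {rule!r}")
    tab = results.copy()
    tab["gene"] = [probe2gene[pr] for pr in tab.index]
    tab["probe_id"] = tab.index
    if rule == "min_p":
        best = tab.sort_values(p_col, kind="mergesort").groupby("gene").head(1)
    else:
        key = tab[["mean_mut", "mean_ctrl"]].mean(axis=1)
        best = tab.assign(_key=-key).sort_values("_key", kind="mergesort").groupby("gene").head(1)
        best = best.drop(columns="_key")
    return best.set_index("gene").sort_index()
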
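"""Expression preprocessing: detection filter, platform intersection,
quantile normalization, log transform, and empirical-Bayes batch adjustment.

The intended order for array data combining two chip versions is
detection_filter -> intersect_platforms -> quantile_normalize ->
(log_transform if raw scale) -> batch_adjust; each step is usable alone.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, SampleMetadata


def detection_filter(x: ExpressionMatrix, alpha: float = 0.05) -> ExpressionMatrix:
    """Keep probes detected (p < alpha) in at least one sample."""
    if x.detection_p is None:
        raise ValueError(
            "matrix has no detection p-values; skip the detection filter "
            "explicitly if your data carries none"
        )
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    keep = (x.detection_p.to_numpy() < alpha).any(axis=1)
    idx = x.values.index[keep]
    return ExpressionMatrix(x.values.loc[idx], x.detection_p.loc[idx])


def intersect_platforms(
    a: ExpressionMatrix, b: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict two matrices to their shared probes, in a common order.

    Mirrors combining two array versions with partially overlapping probe
    content: only probes present on both versions survive.
    """
    common = [g for g in a.gene_ids if g in set(b.gene_ids)]
    if not common:
        raise ValueError("platforms share no probes")
    return a.subset_genes(common), b.subset_genes(common)


def quantile_normalize(x: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common (row-mean) reference distribution.

    The reference is the row-mean of the column-sorted matrix; ties within
    a column receive the mean of the reference values over their rank span,
    making the result deterministic and order-independent.
    """
    v = x.values.to_numpy(float)
    if np.isnan(v).any():
        raise ValueError("quantile normalization requires complete data")
    n_genes, n_samples = v.shape
    if n_samples < 2:
        warnings.warn("single-sample matrix: quantile normalization is a no-op")
        return ExpressionMatrix(x.values.copy(), x.detection_p)
    reference = np.sort(v, axis=0).mean(axis=1)
    out = np.empty_like(v)
    for j in range(n_samples):
        order = np.argsort(v[:, j], kind="mergesort")
        col_sorted = v[order, j]
        ranks = np.empty(n_genes)
        i = 0
        while i < n_genes:
            k = i
            while k + 1 < n_genes and col_sorted[k + 1] == col_sorted[i]:
                k += 1
            ranks[i : k + 1] = reference[i : k + 1].mean()
            i = k + 1
        out[order, j] = ranks
    return ExpressionMatrix(
        pd.DataFrame(out, index=x.values.index, columns=x.values.columns),
        x.detection_p,
    )


def log_transform(x: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """Elementwise log2(x + offset); stands in for a variance-stabilizing
    transform when data arrive on the raw intensity scale."""
    v = x.values.to_numpy(float) + offset
    if (v <= 0).any():
        i, j = np.argwhere(v <= 0)[0]
        raise ValueError(
            f"non-positive value after offset at gene {x.gene_ids[i]!r}, "
            f"sample {x.sample_ids[j]!r}"
        )
    return ExpressionMatrix(
        pd.DataFrame(np.log2(v), index=x.values.index, columns=x.values.columns),
        x.detection_p,
    )


def _condition_fit(v: np.ndarray, cond: np.ndarray) -> np.ndarray:
    """Per-gene fitted condition (genotype x age) cell means."""
    fit = np.zeros_like(v)
    for c in np.unique(cond):
        mask = cond == c
        fit[:, mask] = v[:, mask].mean(axis=1, keepdims=True)
    return fit


def batch_adjust(
    x: ExpressionMatrix,
    meta: SampleMetadata,
    mode: str = "location_scale_eb",
) -> ExpressionMatrix:
    """Remove batch effects while protecting condition (genotype x age) means.

    Per gene, condition cell means are fitted and removed first; per-batch
    location (and, in ``location_scale_eb`` mode, scale) effects are then
    estimated on the standardized residuals, shrunk toward their across-gene
    mean with a parametric empirical-Bayes moment scheme, and subtracted;
    the condition structure is restored afterwards.

    A single batch label is the identity transform.  Batches confounded 1:1
    with condition raise, as the batch effect is then unidentifiable.
    """
    if mode not in ("location_scale_eb", "location_only"):
        raise ValueError(f"unknown mode {mode!r}")
    meta = meta.aligned_to(x)
    batch = meta.table["batch"].to_numpy()
    cond = (meta.table["genotype"].astype(str) + ":" + meta.table["age"].astype(str)).to_numpy()
    batches = np.unique(batch)
    if len(batches) == 1:
        return ExpressionMatrix(x.values.copy(), x.detection_p)
    for b in batches:
        if (batch == b).sum() < 2:
            raise ValueError(f"batch {b!r} has fewer than 2 samples")
        if len(np.unique(cond[batch == b])) == 1 and len(np.unique(cond)) > 1:
            # every sample of this batch sits in one condition cell: check
            # whether that cell also only occurs in this batch
            c = cond[batch == b][0]
            if set(batch[cond == c]) == {b}:
                raise ValueError(
                    f"batch {b!r} is confounded 1:1 with condition {c!r}; "
                    "batch effect unidentifiable"
                )

    v = x.values.to_numpy(float)
    cond_fit = _condition_fit(v, cond)
    resid = v - cond_fit
    sigma = resid.std(axis=1, ddof=1)
    sigma[sigma == 0] = 1.0
    z = resid / sigma[:, None]

    gamma_hat = np.stack([z[:, batch == b].mean(axis=1) for b in batches], axis=1)
    delta_hat = np.stack(
        [z[:, batch == b].var(axis=1, ddof=1) for b in batches], axis=1
    )
    delta_hat = np.clip(delta_hat, 1e-8, None)

    if mode == "location_scale_eb":
        n_b = np.array([(batch == b).sum() for b in batches], dtype=float)
        # parametric moment-matched priors: gamma_gb ~ N(gbar_b, tau2_b),
        # delta2_gb ~ InvGamma(a_b, b_b)
        gbar = gamma_hat.mean(axis=0)
        tau2 = np.clip(gamma_hat.var(axis=0, ddof=1), 1e-8, None)
        gamma_star = (n_b * tau2 * gamma_hat + delta_hat * gbar) / (
            n_b * tau2 + delta_hat
        )
        dbar = delta_hat.mean(axis=0)
        s2 = np.clip(delta_hat.var(axis=0, ddof=1), 1e-12, None)
        a_prior = (2.0 * s2 + dbar**2) / s2
        b_prior = (dbar * s2 + dbar**3) / s2
        # posterior mean of delta2 under inverse-gamma prior with the
        # batch sample sum of squares (single moment step, no iteration)
        ss = delta_hat * (n_b - 1.0)
        delta_star = (0.5 * ss + b_prior) / (0.5 * n_b + a_prior - 1.0)
        delta_star = np.clip(delta_star, 1e-8, None)
    else:
        gamma_star = gamma_hat
        delta_star = np.ones_like(delta_hat)

    adj = z.copy()
    for j, b in enumerate(batches):
        mask = batch == b
        adj[:, mask] = (z[:, mask] - gamma_star[:, [j]]) / np.sqrt(delta_star[:, [j]])
    out = adj * sigma[:, None] + cond_fit
    return ExpressionMatrix(
        pd.DataFrame(out, index=x.values.index, columns=x.values.columns),
        x.detection_p,
    )
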
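"""Weighted gene co-expression network construction and module detection.

Adjacency is a power of the Pearson correlation (|cor|^beta unsigned,
((1+cor)/2)^beta signed); the soft power beta is picked by the approximate
scale-free topology criterion (linear fit of log10 frequency vs log10
connectivity over equal-width connectivity bins).  Topological overlap combines direct
adjacency with shared-neighbour weight; modules come from average-linkage
clustering of the TOM dissimilarity with a static height cut and a minimum
module size, each module summarized by its eigengene (first principal
component over samples), which can then be correlated with sample traits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .datatypes import ExpressionMatrix, ModuleSet, SampleMetadata


@dataclass(frozen=True)
class NetworkParams:
    """Tunables for network construction and module detection."""

    beta: int = 6
    signed: bool = False
    min_module_size: int = 30
    cut_height: float | None = None  # None: 0.995 of maximum merge height
    rsq_target: float = 0.9

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if self.min_module_size < 3:
            raise ValueError("min_module_size must be >= 3")


def _correlation(x: ExpressionMatrix) -> np.ndarray:
    v = x.values.to_numpy(float)
    if v.shape[1] < 4:
        raise ValueError("need >= 4 samples for network construction")
    sd = v.std(axis=1)
    if (sd == 0).any():
        bad = x.values.index[sd == 0][0]
        raise ValueError(f"constant gene {bad!r} has undefined correlation")
    c = np.corrcoef(v)
    return np.clip(c, -1.0, 1.0)


def adjacency(x: ExpressionMatrix, beta: int = 6, signed: bool = False) -> pd.DataFrame:
    """Soft-thresholded co-expression adjacency a_ij in [0, 1]."""
    c = _correlation(x)
    a = ((1.0 + c) / 2.0) ** beta if signed else np.abs(c) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=x.values.index, columns=x.values.index)


def pick_soft_threshold(
    x: ExpressionMatrix,
    candidate_betas=(1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16),
    rsq_target: float = 0.9,
    n_bins: int = 10,
    signed: bool = False,
) -> tuple[int, pd.DataFrame]:
    """Choose the soft power by the approximate scale-free topology criterion.

    For each candidate beta, connectivities k_i = sum_{j != i} a_ij are
    binned into ``n_bins`` equal-width bins and log10(mean frequency) is
    regressed on log10(mean k); the fit index is R^2 signed positive for a
    decreasing (scale-free-like) relationship.  The smallest beta reaching
    ``rsq_target`` wins; if none does, the best-fitting beta is returned
    with a warning.
    """
    if not len(candidate_betas):
        raise ValueError("candidate beta list is empty")
    rows = []
    for beta in candidate_betas:
        a = adjacency(x, beta=beta, signed=signed).to_numpy()
        k = a.sum(axis=1) - 1.0
        rows.append({"beta": beta, "signed_rsq": _scale_free_fit(k, n_bins),
                     "mean_k": float(k.mean()), "max_k": float(k.max())})
    fit = pd.DataFrame(rows)
    ok = fit[fit["signed_rsq"] >= rsq_target]
    if len(ok):
        beta = int(ok["beta"].iloc[0])
    else:
        beta = int(fit.loc[fit["signed_rsq"].fillna(-2.0).idxmax(), "beta"])
        warnings.warn(
            f"no candidate beta reaches signed R^2 {rsq_target}; "
            f"using best fit beta={beta}"
        )
    return beta, fit


def _scale_free_fit(k: np.ndarray, n_bins: int) -> float:
    """Signed R^2 of log10 frequency vs log10 mean connectivity.

    Connectivities are discretized into ``n_bins`` equal-width bins over
    their observed range; empty bins are dropped.
    """
    k = k[k > 0]
    if k.size < 3 or k.max() == k.min():
        raise ValueError("degenerate connectivity distribution")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, n_bins - 1)
    log_k, log_f = [], []
    n = k.size
    for b in range(n_bins):
        mask = which == b
        if not mask.any():
            continue
        log_k.append(np.log10(k[mask].mean()))
        log_f.append(np.log10(mask.sum() / n))
    if len(log_k) < 3:
        raise ValueError("fewer than 3 non-empty connectivity bins")
    res = stats.linregress(log_k, log_f)
    if not np.isfinite(res.rvalue):
        return float("nan")
    # scale-free topology implies a *negative* slope; the fit index is
    # positive when the log-log relationship is decreasing
    return float(res.rvalue**2 * -np.sign(res.slope))


def tom_similarity(a: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Topological overlap matrix.

    omega_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) for i != j with
    l_ij = sum_{u != i,j} a_iu a_uj and k_i = sum_{u != i} a_iu; unit
    diagonal.
    """
    is_frame = isinstance(a, pd.DataFrame)
    m = a.to_numpy(float) if is_frame else np.asarray(a, float)
    if m.shape[0] != m.shape[1] or not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    a0 = m.copy()
    np.fill_diagonal(a0, 0.0)
    k = a0.sum(axis=1)
    l = a0 @ a0  # l_ij for i != j once diagonal contributions are excluded
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        omega = (l + a0) / (kmin + 1.0 - a0)
    omega[~np.isfinite(omega)] = 0.0
    np.fill_diagonal(omega, 1.0)
    if is_frame:
        return pd.DataFrame(omega, index=a.index, columns=a.columns)
    return omega


def _cut_tree(linkage: np.ndarray, cut_height: float | None) -> np.ndarray:
    height = cut_height
    if height is None:
        height = 0.995 * linkage[:, 2].max()
    return fcluster(linkage, t=height, criterion="distance")


def detect_modules(dissim: pd.DataFrame, params: NetworkParams) -> pd.Series:
    """Average-linkage clustering of a dissimilarity matrix into modules.

    The dendrogram is cut at ``params.cut_height`` (default 0.995 of the
    maximum merge height); clusters below ``min_module_size`` become label
    0 (unassigned); surviving modules are renumbered by decreasing size.
    """
    d = dissim.to_numpy(float)
    if not np.allclose(d, d.T, atol=1e-10) or not np.allclose(np.diag(d), 0.0):
        raise ValueError("dissimilarity must be symmetric with zero diagonal")
    linkage = average(squareform(d, checks=False))
    raw = _cut_tree(linkage, params.cut_height)
    labels = _relabel_by_size(raw, params.min_module_size)
    if labels.max() <= 1 and (labels == labels[0]).all():
        warnings.warn("all genes fall into a single cluster at this cut height")
    return pd.Series(labels, index=dissim.index, name="module")


def _relabel_by_size(raw: np.ndarray, min_size: int) -> np.ndarray:
    sizes = pd.Series(raw).value_counts()
    keep = sizes[sizes >= min_size].index
    order = sizes.loc[keep].sort_values(ascending=False).index
    mapping = {old: i + 1 for i, old in enumerate(order)}
    return np.array([mapping.get(r, 0) for r in raw], dtype=int)


def refine_modules_kme(
    x: ExpressionMatrix,
    labels: pd.Series,
    kme_threshold: float = 0.45,
    min_module_size: int = 30,
    n_iter: int = 3,
) -> pd.Series:
    """Refine a module assignment by module membership (kME).

    Each gene is reassigned to the module whose eigengene it correlates
    with most strongly (|cor|, unsigned), provided that correlation reaches
    ``kme_threshold``; genes below threshold for every module become
    unassigned.  Eigengenes are recomputed each iteration until labels
    stabilize; modules falling below ``min_module_size`` are dissolved at
    the end.  This plays the role of the dynamic tree cut's partitioning-
    around-medoids stage: the static height cut seeds module cores, kME
    reassignment grows and cleans them.
    """
    labels = labels.reindex(x.values.index).astype(int)
    v = x.values.to_numpy(float)
    vz = (v - v.mean(axis=1, keepdims=True)) / v.std(axis=1, ddof=1, keepdims=True)
    for _ in range(n_iter):
        if (labels != 0).sum() == 0:
            break
        mods = module_eigengenes(x, labels)
        ids = np.array(mods.module_ids)
        eig = mods.eigengenes.to_numpy(float)
        ez = (eig - eig.mean(axis=1, keepdims=True)) / eig.std(axis=1, ddof=1, keepdims=True)
        kme = np.abs(vz @ ez.T / (v.shape[1] - 1))
        best = kme.argmax(axis=1)
        best_val = kme.max(axis=1)
        new = pd.Series(
            np.where(best_val >= kme_threshold, ids[best], 0), index=labels.index
        )
        if (new == labels).all():
            break
        labels = new
    sizes = labels.value_counts()
    for m in sizes.index:
        if m != 0 and sizes[m] < min_module_size:
            labels[labels == m] = 0
    # renumber surviving modules by decreasing size, 0 stays unassigned
    arr = labels.to_numpy()
    sizes = pd.Series(arr[arr != 0]).value_counts()
    mapping = {old: i + 1 for i, old in enumerate(sizes.index)}
    mapping[0] = 0
    return pd.Series([mapping[v] for v in arr], index=labels.index, name="module")


_SEED_CUT_FRACTIONS = (0.990, 0.992, 0.994, 0.995, 0.996, 0.997, 0.998, 0.999)


def _seed_module_cores(tom: pd.DataFrame, core_size: int) -> pd.Series:
    """Seed module cores from the TOM dendrogram.

    The static cut is evaluated on a fixed grid of heights (fractions of
    the maximum merge height); the height yielding the most clusters of at
    least ``core_size`` genes wins (ties: the lowest such height).  This is
    a deterministic, simplified stand-in for a dynamic cut: modules join
    the background blob at slightly different heights, and no single
    fraction separates them all.
    """
    d = 1.0 - tom.to_numpy()
    np.fill_diagonal(d, 0.0)
    linkage = average(squareform(d, checks=False))
    hmax = linkage[:, 2].max()
    best_labels, best_n = None, -1
    for frac in _SEED_CUT_FRACTIONS:
        raw = fcluster(linkage, t=frac * hmax, criterion="distance")
        lab = _relabel_by_size(raw, core_size)
        n_cores = int(lab.max())
        if n_cores > best_n:
            best_labels, best_n = lab, n_cores
    return pd.Series(best_labels, index=tom.index, name="module")


def find_modules(
    x: ExpressionMatrix,
    params: NetworkParams | None = None,
    core_size: int | None = None,
    kme_threshold: float | None = None,
    merge_dissim: float = 0.25,
) -> ModuleSet:
    """End-to-end module detection: adjacency -> TOM -> multi-height core
    seeding -> kME refinement -> merge of near-duplicate modules ->
    eigengenes.

    Cores of at least ``core_size`` genes (default half of
    ``min_module_size``, at least 10) are seeded from the TOM dendrogram;
    kME refinement then assigns every gene to its best-matching eigengene
    and enforces the final minimum module size.  The default kME threshold
    scales with correlation noise: max(0.3, 2.5 / sqrt(n_samples - 3)).
    """
    params = params or NetworkParams()
    if core_size is None:
        core_size = max(params.min_module_size // 2, 10)
    if kme_threshold is None:
        kme_threshold = max(0.3, 2.5 / np.sqrt(x.shape[1] - 3))
    a = adjacency(x, beta=params.beta, signed=params.signed)
    tom = tom_similarity(a)
    labels = _seed_module_cores(tom, core_size)
    labels = refine_modules_kme(
        x, labels, kme_threshold=kme_threshold, min_module_size=params.min_module_size
    )
    mods = module_eigengenes(x, labels)
    if merge_dissim > 0 and len(mods.module_ids) > 1:
        mods = merge_close_modules(mods, x, merge_dissim)
    return mods


def module_eigengenes(x: ExpressionMatrix, labels: pd.Series) -> ModuleSet:
    """Per-module eigengene: first right singular vector over samples.

    Genes are z-scored across samples first; the eigengene is scaled to
    unit variance and sign-oriented to correlate positively with the
    module's mean z-scored expression.  ``var_explained`` is the first
    squared singular value over the total.
    """
    labels = labels.reindex(x.values.index)
    if labels.isna().any():
        raise ValueError("labels missing for some genes")
    module_ids = sorted(int(m) for m in labels.unique() if m != 0)
    rows, var_exp = [], {}
    v = x.values.to_numpy(float)
    for m in module_ids:
        idx = np.flatnonzero(labels.to_numpy() == m)
        if idx.size == 0:
            raise ValueError(f"module {m} has no genes")
        z = v[idx]
        mu = z.mean(axis=1, keepdims=True)
        sd = z.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        z = (z - mu) / sd
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        e = vt[0]
        mean_expr = z.mean(axis=0)
        if np.corrcoef(e, mean_expr)[0, 1] < 0:
            e = -e
        e = e / e.std(ddof=1)
        rows.append(pd.Series(e, index=x.values.columns, name=m))
        var_exp[m] = float(s[0] ** 2 / (s**2).sum())
    eig = pd.DataFrame(rows) if rows else pd.DataFrame(columns=x.values.columns)
    eig.index.name = "module"
    return ModuleSet(labels.astype(int), eig, pd.Series(var_exp, dtype=float))


def correlation_test(r: float, n: int) -> tuple[float, float]:
    """Two-sided Student test of a Pearson correlation.

    t = r * sqrt((n-2)/(1-r^2)) with n-2 degrees of freedom.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        return np.inf if r > 0 else -np.inf, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(t), float(2.0 * stats.t.sf(abs(t), n - 2))


def module_trait_correlation(
    mods: ModuleSet, meta: SampleMetadata, trait_name: str = "trait"
) -> pd.DataFrame:
    """Pearson correlation of every module eigengene with a numeric trait."""
    samples = list(mods.eigengenes.columns)
    trait = meta.table.loc[samples, trait_name].to_numpy(float)
    if len(samples) < 4:
        raise ValueError("need >= 4 samples")
    if np.std(trait) == 0:
        raise ValueError(f"trait {trait_name!r} is constant")
    rows = []
    n = len(samples)
    for m in mods.module_ids:
        r = float(np.corrcoef(mods.eigengenes.loc[m].to_numpy(float), trait)[0, 1])
        t, p = correlation_test(r, n)
        rows.append({"module": m, "r": r, "t": t, "p": p, "n": n})
    return pd.DataFrame(rows).set_index("module")


def merge_close_modules(
    mods: ModuleSet, x: ExpressionMatrix, max_dissim: float = 0.25
) -> ModuleSet:
    """Iteratively merge module pairs whose eigengene dissimilarity
    (1 - cor) falls below ``max_dissim``, recomputing eigengenes after each
    merge.  The merged module keeps the smaller id."""
    labels = mods.labels.copy()
    while True:
        current = module_eigengenes(x, labels)
        ids = current.module_ids
        if len(ids) < 2:
            return current
        eig = current.eigengenes.to_numpy(float)
        c = np.corrcoef(eig)
        best, best_d = None, max_dissim
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                d = 1.0 - c[i, j]
                if d < best_d:
                    best, best_d = (ids[i], ids[j]), d
        if best is None:
            return current
        keep, drop = min(best), max(best)
        labels[labels == drop] = keep
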
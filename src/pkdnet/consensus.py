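"""Consensus modules across condition groups and eigengene-network
preservation.

Consensus module detection computes a TOM per condition group, rescales
each group's TOM so a chosen upper quantile matches the first group's,
takes the elementwise minimum as the consensus similarity, and clusters
1 - consensus.  Per-group eigengene networks A_ij = (1 + cor(E_i, E_j))/2
are compared via the preservation density D = 1 - mean |A1_ij - A2_ij|
over module pairs; meta-modules are branches of the eigengene dendrogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .datatypes import ExpressionMatrix, ModuleSet
from .network import (
    NetworkParams,
    _seed_module_cores,
    adjacency,
    module_eigengenes,
    tom_similarity,
)


@dataclass
class EigengeneNetwork:
    """Module x module adjacency A_ij = (1 + cor(E_i, E_j)) / 2 within one
    condition group."""

    condition: str
    adjacency: pd.DataFrame

    def __post_init__(self) -> None:
        a = self.adjacency.to_numpy(float)
        if not np.allclose(a, a.T, atol=1e-10):
            raise ValueError("eigengene network must be symmetric")
        if (a < -1e-10).any() or (a > 1 + 1e-10).any():
            raise ValueError("eigengene adjacency must lie in [0, 1]")

    @property
    def module_ids(self) -> list[int]:
        return [int(m) for m in self.adjacency.index]


def consensus_similarity(
    xs: list[ExpressionMatrix],
    params: NetworkParams | None = None,
    scale_quantile: float = 0.95,
) -> pd.DataFrame:
    """Consensus TOM across groups: elementwise minimum after quantile
    scaling.

    Each group's TOM is multiplicatively rescaled so its
    ``scale_quantile``-quantile (over off-diagonal entries) matches the
    first group's, guarding the minimum against per-group connectivity
    differences.  Identical groups yield their common TOM unchanged.
    """
    if len(xs) < 2:
        raise ValueError("need >= 2 condition groups")
    params = params or NetworkParams()
    genes = xs[0].values.index
    for x in xs[1:]:
        if not x.values.index.equals(genes):
            raise ValueError("all groups must share the same gene ids in order")
    toms = []
    for x in xs:
        a = adjacency(x, beta=params.beta, signed=params.signed)
        toms.append(tom_similarity(a).to_numpy())
    off = ~np.eye(len(genes), dtype=bool)
    ref_q = np.quantile(toms[0][off], scale_quantile)
    scaled = [toms[0]]
    for t in toms[1:]:
        q = np.quantile(t[off], scale_quantile)
        f = ref_q / q if q > 0 else 1.0
        scaled.append(np.clip(t * f, 0.0, 1.0))
    consensus = np.minimum.reduce(scaled)
    np.fill_diagonal(consensus, 1.0)
    return pd.DataFrame(consensus, index=genes, columns=genes)


def consensus_modules(
    xs: list[ExpressionMatrix],
    params: NetworkParams | None = None,
    scale_quantile: float = 0.95,
) -> pd.Series:
    """Consensus module labels across >= 2 condition groups.

    Group TOMs are multiplicatively rescaled so their ``scale_quantile``
    quantiles match the first group's (a robustness step against per-group
    connectivity differences), then combined elementwise by minimum; module
    detection proceeds on 1 - consensus as usual.
    """
    params = params or NetworkParams()
    consensus_df = consensus_similarity(xs, params, scale_quantile)
    core_size = max(params.min_module_size // 2, 10)
    labels = _seed_module_cores(consensus_df, core_size)
    # a "core" swallowing most genes is the unclustered background blob,
    # not a module
    counts = labels.value_counts()
    for m in counts.index:
        if m != 0 and counts[m] > 0.5 * len(labels):
            labels[labels == m] = 0

    labels = _refine_consensus_kme(xs, labels, params.min_module_size)
    return labels


def _refine_consensus_kme(
    xs: list[ExpressionMatrix],
    labels: pd.Series,
    min_module_size: int,
    n_iter: int = 3,
) -> pd.Series:
    """Grow/clean consensus cores by cross-group module membership.

    A gene joins the module whose per-group eigengenes it correlates with
    most strongly on average (mean |kME| across groups); the threshold
    scales with the noise of that mean, max(0.3, 2.5 / sqrt(sum_g (n_g -
    3))).  A module must hold in every group, so the consensus eigengenes
    are recomputed per group each iteration.
    """
    n_eff = sum(x.shape[1] - 3 for x in xs)
    thresh = max(0.3, 2.5 / np.sqrt(max(n_eff, 1)))
    for _ in range(n_iter):
        ids = sorted(m for m in labels.unique() if m != 0)
        if not ids:
            break
        mean_kme = np.zeros((len(labels), len(ids)))
        for x in xs:
            mods = module_eigengenes(x, labels)
            v = x.values.to_numpy(float)
            vz = (v - v.mean(axis=1, keepdims=True)) / v.std(axis=1, ddof=1, keepdims=True)
            eig = mods.eigengenes.loc[ids].to_numpy(float)
            ez = (eig - eig.mean(axis=1, keepdims=True)) / eig.std(axis=1, ddof=1, keepdims=True)
            mean_kme += np.abs(vz @ ez.T / (v.shape[1] - 1))
        mean_kme /= len(xs)
        best = mean_kme.argmax(axis=1)
        best_val = mean_kme.max(axis=1)
        new = pd.Series(
            np.where(best_val >= thresh, np.array(ids)[best], 0), index=labels.index
        )
        if (new == labels).all():
            labels = new
            break
        labels = new
    arr = labels.to_numpy()
    sizes = pd.Series(arr[arr != 0]).value_counts()
    small = [m for m in sizes.index if sizes[m] < min_module_size]
    arr = np.where(np.isin(arr, small), 0, arr)
    sizes = pd.Series(arr[arr != 0]).value_counts()
    mapping = {old: i + 1 for i, old in enumerate(sizes.index)}
    mapping[0] = 0
    return pd.Series([mapping[v] for v in arr], index=labels.index, name="module")


def eigengene_network(
    x: ExpressionMatrix, labels: pd.Series, condition: str
) -> EigengeneNetwork:
    """Eigengene correlation network for one condition's samples."""
    mods = module_eigengenes(x, labels)
    ids = mods.module_ids
    if len(ids) < 2:
        raise ValueError("need >= 2 modules for an eigengene network")
    c = np.corrcoef(mods.eigengenes.to_numpy(float))
    a = (1.0 + np.clip(c, -1.0, 1.0)) / 2.0
    np.fill_diagonal(a, 1.0)
    return EigengeneNetwork(condition, pd.DataFrame(a, index=ids, columns=ids))


def preservation_density(n1: EigengeneNetwork, n2: EigengeneNetwork) -> float:
    """D = 1 - (2 / (m(m-1))) * sum_{i<j} |A1_ij - A2_ij|; 1 = identical."""
    if n1.module_ids != n2.module_ids:
        raise ValueError("eigengene networks cover different module sets")
    m = len(n1.module_ids)
    if m < 2:
        raise ValueError("need >= 2 modules")
    a1 = n1.adjacency.to_numpy(float)
    a2 = n2.adjacency.to_numpy(float)
    iu = np.triu_indices(m, k=1)
    return float(1.0 - np.abs(a1[iu] - a2[iu]).mean())


def meta_modules(net: EigengeneNetwork, cut: float = 0.5) -> pd.Series:
    """Cluster module eigengenes into meta-modules.

    Average-linkage clustering of modules with dissimilarity 1 - cor
    (= 2(1 - A)); branches below ``cut`` form one meta-module.  Meta-module
    ids are ordered by each branch's smallest member module id.
    """
    ids = net.module_ids
    if len(ids) < 2:
        raise ValueError("need >= 2 modules")
    a = net.adjacency.to_numpy(float)
    dissim = 2.0 * (1.0 - a)  # back to 1 - cor
    np.fill_diagonal(dissim, 0.0)
    dissim = np.clip(dissim, 0.0, None)
    linkage = average(squareform(dissim, checks=False))
    raw = fcluster(linkage, t=cut, criterion="distance")
    # deterministic renumbering by smallest module id per branch
    firsts = {}
    for mod, r in zip(ids, raw):
        firsts.setdefault(r, mod)
    order = sorted(firsts, key=lambda r: firsts[r])
    mapping = {r: i + 1 for i, r in enumerate(order)}
    return pd.Series([mapping[r] for r in raw], index=pd.Index(ids, name="module"),
                     name="meta_module")
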
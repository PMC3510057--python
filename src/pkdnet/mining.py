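"""Compendium module mining: signature overlap and misclassification ranking.

Modules mined from a large expression compendium are scored against a
disease signature by hypergeometric overlap (BH-adjusted across modules),
and independently ranked by how well unsupervised clustering of samples on
each module's genes recovers the class labels (genotype, or genotype x
age), the module with the lowest misclassification rate coming first.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist

from .datatypes import EnrichmentResult, ExpressionMatrix, SampleMetadata
from .diffexpr import bh_fdr


def hypergeom_overlap(query, target, universe, set_id: str = "") -> EnrichmentResult:
    """Upper-tail hypergeometric p for the overlap of two gene sets.

    p = P(X >= k) with X ~ Hypergeom(N=|universe|, K=|target|, n=|query|)
    and k = |query ∩ target|.
    """
    query, target, universe = set(query), set(target), set(universe)
    stray = sorted(query - universe)
    if stray:
        raise ValueError(f"query genes outside universe: {stray[:5]}")
    stray = sorted(target - universe)
    if stray:
        raise ValueError(f"target genes outside universe: {stray[:5]}")
    N, K, n = len(universe), len(target), len(query)
    k = len(query & target)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(set_id=set_id, k=k, K=K, n=n, N=N, p=min(max(p, 0.0), 1.0))


def mine_modules(
    compendium_modules: dict[str, set],
    signature,
    universe,
    alpha: float = 0.001,
) -> pd.DataFrame:
    """Overlap-test every compendium module against the signature.

    Returns a table sorted by p with columns k, K, n, N, p, q and
    ``flagged`` marking modules with p < alpha (the headline rule uses the
    unadjusted p at a stringent alpha; q is reported alongside).
    """
    if not compendium_modules:
        raise ValueError("no compendium modules supplied")
    signature = set(signature)
    if not signature:
        raise ValueError("empty signature")
    rows = []
    for name, members in compendium_modules.items():
        r = hypergeom_overlap(signature, members, universe, set_id=str(name))
        rows.append({"module": str(name), "k": r.k, "K": r.K, "n": r.n, "N": r.N, "p": r.p})
    tab = pd.DataFrame(rows).set_index("module")
    tab["q"] = bh_fdr(tab["p"].to_numpy())
    tab["flagged"] = tab["p"] < alpha
    return tab.sort_values("p", kind="mergesort")


def _class_labels(meta: SampleMetadata, samples, classes: str) -> np.ndarray:
    t = meta.table.loc[samples]
    if classes == "genotype":
        lab = t["genotype"].astype(str)
    elif classes == "genotype_x_age":
        lab = t["genotype"].astype(str) + ":" + t["age"].astype(str)
    else:
        raise ValueError(f"unknown class scheme {classes!r}")
    return lab.to_numpy()


def misclassification_rate(
    x: ExpressionMatrix, meta: SampleMetadata, genes, classes: str = "genotype"
) -> float:
    """Fraction of samples misassigned by unsupervised clustering on a
    gene subset.

    Module genes are z-scored, samples clustered by average linkage on
    Euclidean distance and cut into c = number of classes clusters; the
    optimal cluster -> class assignment (exact, via the assignment problem)
    determines the error (n - matched) / n.
    """
    genes = [g for g in genes if g in set(x.gene_ids)]
    if len(genes) < 2:
        raise ValueError("need >= 2 module genes present in the matrix")
    samples = x.sample_ids
    y = _class_labels(meta, samples, classes)
    class_names, y_idx = np.unique(y, return_inverse=True)
    c = len(class_names)
    counts = np.bincount(y_idx)
    if (counts < 2).any():
        small = class_names[counts < 2]
        raise ValueError(f"classes with < 2 samples: {list(small)}")
    v = x.values.loc[genes].to_numpy(float)
    sd = v.std(axis=1, ddof=1)
    sd[sd == 0] = 1.0
    z = ((v - v.mean(axis=1, keepdims=True)) / sd[:, None]).T  # samples x genes
    linkage = average(pdist(z))
    clusters = fcluster(linkage, t=c, criterion="maxclust") - 1
    n_clusters = clusters.max() + 1
    contingency = np.zeros((max(n_clusters, c), c))
    for cl, cls in zip(clusters, y_idx):
        contingency[cl, cls] += 1
    row, col = linear_sum_assignment(-contingency)
    matched = contingency[row, col].sum()
    return float((len(samples) - matched) / len(samples))


def rank_by_misclassification(
    x: ExpressionMatrix,
    meta: SampleMetadata,
    modules: dict[str, set],
    classes: str = "genotype",
) -> pd.DataFrame:
    """Rank modules ascending by misclassification rate.

    Ties are broken by module size (larger first), then by module name for
    determinism.
    """
    rows = []
    for name, genes in modules.items():
        present = [g for g in genes if g in set(x.gene_ids)]
        rate = misclassification_rate(x, meta, present, classes=classes)
        rows.append({"module": str(name), "misclassification_rate": rate,
                     "n_genes": len(present)})
    tab = pd.DataFrame(rows)
    tab = tab.sort_values(
        ["misclassification_rate", "n_genes", "module"],
        ascending=[True, False, True],
        kind="mergesort",
    ).set_index("module")
    tab["rank"] = np.arange(1, len(tab) + 1)
    return tab


def project_samples(x: ExpressionMatrix, gene_subset) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal-axis coordinates of samples on a gene subset.

    Genes are z-scored across samples; the SVD of the samples x genes
    matrix gives sample coordinates on the leading axes.  Returns
    (coordinates with columns PC1, PC2, variance fractions).
    """
    genes = [g for g in gene_subset if g in set(x.gene_ids)]
    if not genes:
        raise ValueError("gene subset does not intersect the matrix")
    v = x.values.loc[genes].to_numpy(float)
    sd = v.std(axis=1, ddof=1)
    sd[sd == 0] = 1.0
    z = ((v - v.mean(axis=1, keepdims=True)) / sd[:, None]).T
    u, s, vt = np.linalg.svd(z - z.mean(axis=0), full_matrices=False)
    var_frac = s**2 / (s**2).sum() if (s**2).sum() > 0 else s * 0
    n_axes = min(2, len(s))
    coords = u[:, :n_axes] * s[:n_axes]
    cols = [f"PC{i+1}" for i in range(n_axes)]
    return pd.DataFrame(coords, index=x.values.columns, columns=cols), var_frac[:n_axes]
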
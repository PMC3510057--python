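"""Urinary metabolomics: feature filtering, accurate-mass adduct
annotation, compound-set enrichment, and PLS-VIP metabolite ranking.

Features pass the differential filter when both group means exceed a
floor, the Welch-t BH-q (per ionization mode) is below threshold, and the
fold change between group means exceeds threshold.  Annotation matches
observed m/z against adduct-transformed monoisotopic masses within a ppm
tolerance; compound-set enrichment reuses the hypergeometric overlap test;
PLS-VIP ranks features by their importance in a PLS1 model predicting
genotype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CompoundRecord, EnrichmentResult, PeakTable, SampleMetadata
from .diffexpr import bh_fdr
from .mining import hypergeom_overlap


@dataclass(frozen=True)
class AdductRule:
    """Mass shift (Da) from neutral monoisotopic mass M to observed m/z."""

    name: str
    mode: str
    delta: float


# Singly-charged adducts and neutral losses; proton-mass convention
# (electron mass neglected, consistent at 5 ppm for m/z > 50).
ADDUCT_RULES = (
    AdductRule("+H", "positive", +1.007276),
    AdductRule("+NH4", "positive", +18.033823),
    AdductRule("+Na", "positive", +22.989218),
    AdductRule("+H-H2O", "positive", -17.003289),
    AdductRule("+H-2H2O", "positive", -35.013854),
    AdductRule("-H", "negative", -1.007276),
    AdductRule("-H2O-H", "negative", -19.017841),
    AdductRule("+Na-2H", "negative", +20.974666),
    AdductRule("+Cl", "negative", +34.969402),
    AdductRule("+K-2H", "negative", +36.948058),
)


def filter_features(
    pt: PeakTable,
    meta: SampleMetadata,
    min_mean: float = 0.1,
    q_thresh: float = 0.02,
    fc_thresh: float = 2.0,
) -> tuple[PeakTable, pd.DataFrame]:
    """Differential-feature filter.

    Keeps features with group means > ``min_mean`` in BOTH genotype groups,
    BH-q (Welch two-sided t on intensities, adjusted per ionization mode)
    < ``q_thresh``, and max(mean ratio, inverse ratio) > ``fc_thresh``.
    Returns (filtered table, per-feature statistics table).
    """
    meta = meta.table
    mut = [s for s in pt.intensities.columns if meta.loc[s, "genotype"] == "mutant"]
    ctrl = [s for s in pt.intensities.columns if meta.loc[s, "genotype"] == "control"]
    if len(mut) < 3 or len(ctrl) < 3:
        raise ValueError("need >= 3 samples per genotype group")
    vm = pt.intensities[mut].to_numpy(float)
    vc = pt.intensities[ctrl].to_numpy(float)
    mean_mut = vm.mean(axis=1)
    mean_ctrl = vc.mean(axis=1)
    t, p = stats.ttest_ind(vm, vc, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    stats_tab = pd.DataFrame(
        {
            "mode": pt.features["mode"],
            "mean_mut": mean_mut,
            "mean_ctrl": mean_ctrl,
            "p": p,
        },
        index=pt.features.index,
    )
    q = np.full(len(stats_tab), np.nan)
    for mode in stats_tab["mode"].unique():
        mask = (stats_tab["mode"] == mode).to_numpy()
        q[mask] = bh_fdr(stats_tab.loc[mask, "p"].to_numpy())
    stats_tab["q"] = q
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            (mean_mut > 0) & (mean_ctrl > 0),
            np.maximum(mean_mut / mean_ctrl, mean_ctrl / mean_mut),
            np.inf,
        )
    stats_tab["fold_change"] = ratio
    keep = (
        (mean_mut > min_mean)
        & (mean_ctrl > min_mean)
        & (stats_tab["q"].to_numpy() < q_thresh)
        & (ratio > fc_thresh)
    )
    stats_tab["retained"] = keep
    return pt.subset(pt.features.index[keep]), stats_tab


def annotate_mz(
    pt: PeakTable,
    db: list[CompoundRecord],
    rules=ADDUCT_RULES,
    tol_ppm: float = 5.0,
) -> pd.DataFrame:
    """Accurate-mass annotation of features against a compound database.

    For each (feature, mode-matching adduct rule, compound) the theoretical
    m/z is M + delta; a match requires |observed - theoretical| /
    theoretical * 1e6 <= ``tol_ppm``.  All matches are returned, sorted by
    feature then |ppm_error| (no unique-assignment heuristic).
    """
    if not db:
        raise ValueError("empty compound database")
    rows = []
    by_mode: dict[str, list[AdductRule]] = {}
    for r in rules:
        by_mode.setdefault(r.mode, []).append(r)
    for fid, feat in pt.features.iterrows():
        mz = float(feat["mz"])
        for rule in by_mode.get(feat["mode"], []):
            for comp in db:
                theo = comp.monoisotopic_mass + rule.delta
                if theo <= 0:
                    continue
                ppm = (mz - theo) / theo * 1e6
                if abs(ppm) <= tol_ppm:
                    rows.append(
                        {
                            "feature_id": fid,
                            "compound_id": comp.compound_id,
                            "adduct": rule.name,
                            "theoretical_mz": theo,
                            "ppm_error": ppm,
                        }
                    )
    out = pd.DataFrame(rows, columns=["feature_id", "compound_id", "adduct",
                                      "theoretical_mz", "ppm_error"])
    if len(out):
        out["_abs"] = out["ppm_error"].abs()
        out = out.sort_values(["feature_id", "_abs"], kind="mergesort")
        out = out.drop(columns="_abs").reset_index(drop=True)
    return out


def compound_enrichment(
    annotated,
    pathways: dict[str, set],
    universe,
) -> pd.DataFrame:
    """Hypergeometric pathway enrichment of annotated differential compounds.

    Reports, per pathway, the ratio k/K (differentially detected compounds
    over compounds in the pathway) alongside p and BH q.
    """
    annotated = set(annotated)
    universe = set(universe)
    if not annotated <= universe:
        raise ValueError(f"annotated compounds outside universe: "
                         f"{sorted(annotated - universe)[:5]}")
    rows = []
    for name, members in pathways.items():
        if not set(members) <= universe:
            raise ValueError(f"pathway {name!r} has compounds outside the universe")
        r = hypergeom_overlap(annotated, members, universe, set_id=name)
        rows.append(
            {"pathway": name, "k": r.k, "K": r.K, "n": r.n, "N": r.N,
             "ratio": f"{r.k}/{r.K}", "p": r.p}
        )
    tab = pd.DataFrame(rows).set_index("pathway")
    tab["q"] = bh_fdr(tab["p"].to_numpy())
    return tab.sort_values("p", kind="mergesort")


def pls_vip(
    pt: PeakTable, meta: SampleMetadata, n_components: int = 2
) -> pd.DataFrame:
    """Variable importance in projection from a PLS1 genotype model.

    Intensities are standardized per feature; a PLS1 regression of the 0/1
    genotype label on the features is fitted with ``n_components`` latent
    components, and VIP_j = sqrt(p * sum_a SS_a (w_aj/||w_a||)^2 /
    sum_a SS_a), SS_a being the label variance explained by component a.
    Features are returned sorted by VIP descending.
    """
    from sklearn.cross_decomposition import PLSRegression

    y = meta.table.loc[pt.intensities.columns, "trait"].to_numpy(float)
    if len(np.unique(y)) < 2 or min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need >= 2 samples per class")
    X = pt.intensities.to_numpy(float).T  # samples x features
    n, p = X.shape
    if n_components > min(n - 1, p):
        raise ValueError(f"n_components={n_components} exceeds data rank")
    model = PLSRegression(n_components=n_components, scale=True)
    model.fit(X, y)
    w = model.x_weights_  # p x a
    t_scores = model.x_scores_  # n x a
    q_load = model.y_loadings_.ravel()  # a
    ss = (q_load**2) * (t_scores**2).sum(axis=0)  # label variance per component
    w_norm = w / np.linalg.norm(w, axis=0, keepdims=True)
    vip = np.sqrt(p * (w_norm**2 @ ss) / ss.sum())
    out = pd.DataFrame({"vip": vip}, index=pt.features.index.rename("feature_id"))
    return out.sort_values("vip", ascending=False, kind="mergesort")
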
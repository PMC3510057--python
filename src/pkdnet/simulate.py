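"""Seeded generators for every input the pipeline consumes.

The generators emulate the structure of a two-age (P12/P14), two-genotype
(mutant/control) kidney microarray study: co-expression modules are planted
as latent single-factor drivers, genotype and age act as mean shifts on the
drivers, batches add per-batch constant offsets, and urinary metabolomics
peak tables are built from adduct-transformed monoisotopic masses with ppm
jitter.  Ground truth (module labels, planted features, effects) is always
returned alongside the data so recovery can be scored.

Expression is generated directly on the log2 scale — the scale the rest of
the pipeline assumes after variance stabilization — so no inverse transform
is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CompoundRecord, ExpressionMatrix, PeakTable, SampleMetadata

# Monoisotopic element masses (Da)
ELEMENT_MASSES = {
    "C": 12.000000,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
    "P": 30.97376151,
}

AGES = ("P12", "P14")
GROUPS = tuple((a, g) for a in AGES for g in ("mutant", "control"))

_PATHWAY_VOCAB = (
    "tyrosine metabolism",
    "purine metabolism",
    "oxidative phosphorylation",
    "aminoacyl-tRNA biosynthesis",
    "fatty acid oxidation",
    "glycolysis",
    "bile acid biosynthesis",
    "urea cycle",
)


@dataclass(frozen=True)
class ModulePlan:
    """Recipe for one planted co-expression module.

    Genes in the module load on a shared latent driver; ``genotype_effect``
    and ``age_effect`` are standardized mean shifts applied to that driver
    (mutant vs control and P14 vs P12 respectively).  ``genotype_effect``
    may be a single number or an (effect at P12, effect at P14) pair for a
    disease effect that grows with age.
    """

    module_id: int
    size: int
    loading_range: tuple[float, float] = (0.4, 0.95)
    genotype_effect: float | tuple[float, float] = 0.0
    age_effect: float = 0.0
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.module_id < 1:
            raise ValueError("module_id must be >= 1")
        if self.size < 2:
            raise ValueError("module size must be >= 2")
        lo, hi = self.loading_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("loading_range must lie within (0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def _group_layout(groups: dict[tuple[str, str], int]) -> pd.DataFrame:
    rows = []
    i = 0
    for (age, geno), n in groups.items():
        if n < 2:
            raise ValueError(f"group {(age, geno)} needs >= 2 samples, got {n}")
        for _ in range(int(n)):
            rows.append({"sample_id": f"S{i:03d}", "age": age, "genotype": geno})
            i += 1
    return pd.DataFrame(rows).set_index("sample_id")


def _driver(rng, meta: pd.DataFrame, genotype_effect, age_effect: float):
    n = len(meta)
    e = rng.standard_normal(n)
    if isinstance(genotype_effect, tuple):
        ge12, ge14 = genotype_effect
    else:
        ge12 = ge14 = genotype_effect
    mut = (meta["genotype"] == "mutant").to_numpy(float)
    p14 = (meta["age"] == "P14").to_numpy(float)
    e += mut * np.where(p14 == 1.0, ge14, ge12)
    e += age_effect * p14
    return e


def gen_expression(
    plans: list[ModulePlan],
    n_background: int,
    groups: dict[tuple[str, str], int] | None = None,
    n_batches: int = 2,
    batch_shift_sd: float = 0.0,
    detected_background_fraction: float = 0.5,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SampleMetadata, pd.Series]:
    """Simulate a genes x samples study with planted modules.

    Gene g in module m is x_g = lambda_g * E_m + eps, with lambda_g drawn
    uniformly from the plan's loading range and E_m the module driver
    (standard normal per sample plus genotype/age shifts).  Background genes
    are pure noise.  Batches (assigned round-robin within each group) add a
    per-batch constant; detection p-values are small for module genes and
    ~Uniform(0,1) for a configurable fraction of background genes.

    Returns (matrix, metadata, true_labels) with true_labels a per-gene
    module id (0 = background).
    """
    if groups is None:
        groups = {g: 8 for g in GROUPS}
    ids = [p.module_id for p in plans]
    if len(set(ids)) != len(ids):
        raise ValueError("module ids in plans must be distinct")
    rng = np.random.default_rng(seed)
    meta = _group_layout(groups)
    n_samples = len(meta)
    n_mod = sum(p.size for p in plans)
    n_genes = n_mod + n_background

    # round-robin batch assignment inside each group keeps batch and
    # condition unconfounded by construction
    batch = np.empty(n_samples, dtype=object)
    for age, geno in groups:
        idx = np.flatnonzero(
            (meta["age"] == age).to_numpy() & (meta["genotype"] == geno).to_numpy()
        )
        for j, k in enumerate(idx):
            batch[k] = f"B{j % n_batches}"
    meta["batch"] = batch
    # alternate test/validation within groups
    split = np.where(np.arange(n_samples) % 2 == 0, "test", "validation")
    meta["split"] = split

    values = np.empty((n_genes, n_samples))
    labels = np.zeros(n_genes, dtype=int)
    row = 0
    for plan in plans:
        e = _driver(rng, meta, plan.genotype_effect, plan.age_effect)
        lam = rng.uniform(*plan.loading_range, size=plan.size)
        eps = rng.standard_normal((plan.size, n_samples)) * plan.noise_sd
        values[row : row + plan.size] = lam[:, None] * e[None, :] + eps
        labels[row : row + plan.size] = plan.module_id
        row += plan.size
    values[row:] = rng.standard_normal((n_background, n_samples))

    if batch_shift_sd > 0:
        shifts = {b: rng.normal(0.0, batch_shift_sd) for b in sorted(set(batch))}
        values += np.array([shifts[b] for b in batch])[None, :]

    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    sample_ids = list(meta.index)
    # detection p: expressed genes near zero; a fraction of background genes
    # are "undetected" (uniform p, mostly failing the 0.05 filter)
    detp = rng.uniform(0.0, 0.04, size=(n_genes, n_samples))
    n_undetected = int(round((1.0 - detected_background_fraction) * n_background))
    if n_undetected > 0:
        und = rng.choice(n_background, size=n_undetected, replace=False) + n_mod
        detp[und] = rng.uniform(0.05, 1.0, size=(n_undetected, n_samples))

    x = ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids),
        pd.DataFrame(detp, index=gene_ids, columns=sample_ids),
    )
    sm = SampleMetadata(meta)
    return x, sm, pd.Series(labels, index=gene_ids, name="truth_module")


def gen_compendium(
    shared_plans: list[ModulePlan],
    n_datasets: int,
    n_background: int = 200,
    n_samples_per_dataset: int = 20,
    per_dataset_effects: list[float] | None = None,
    seed: int = 0,
) -> tuple[list[ExpressionMatrix], pd.Series]:
    """Simulate a multi-dataset compendium sharing module structure.

    All datasets share gene ids and true module memberships; each dataset
    redraws the latent drivers (optionally shifted by a per-dataset effect
    applied to a two-group split of its samples), so modules are
    co-expressed everywhere while condition associations vary.
    """
    if not shared_plans:
        raise ValueError("at least one module plan is required")
    if n_datasets < 2:
        raise ValueError("a compendium needs >= 2 datasets")
    rng = np.random.default_rng(seed)
    if per_dataset_effects is None:
        per_dataset_effects = [0.0] * n_datasets
    n_mod = sum(p.size for p in shared_plans)
    n_genes = n_mod + n_background
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    labels = np.zeros(n_genes, dtype=int)
    row = 0
    for plan in shared_plans:
        labels[row : row + plan.size] = plan.module_id
        row += plan.size

    # loadings are a gene property, shared across datasets
    loadings = {}
    row = 0
    for plan in shared_plans:
        loadings[plan.module_id] = (
            slice(row, row + plan.size),
            rng.uniform(*plan.loading_range, size=plan.size),
        )
        row += plan.size

    datasets = []
    for d in range(n_datasets):
        ns = n_samples_per_dataset
        group = np.repeat([0.0, 1.0], [ns - ns // 2, ns // 2])
        values = np.empty((n_genes, ns))
        for plan in shared_plans:
            sl, lam = loadings[plan.module_id]
            # association with the dataset's condition varies per module:
            # random sign, magnitude set by the per-dataset effect
            assoc = per_dataset_effects[d] * rng.choice([-1.0, 1.0])
            e = rng.standard_normal(ns) + assoc * group
            values[sl] = lam[:, None] * e[None, :] + rng.standard_normal(
                (plan.size, ns)
            ) * plan.noise_sd
        values[n_mod:] = rng.standard_normal((n_background, ns))
        cols = [f"D{d}_S{i:02d}" for i in range(ns)]
        datasets.append(ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=cols)))
    return datasets, pd.Series(labels, index=gene_ids, name="truth_module")


def gen_meta_module_study(
    n_modules: int = 8,
    decoupled_module: int = 8,
    block_rho: float = 0.95,
    decoupled_rho: float = 0.0,
    module_size: int = 40,
    n_background: int = 100,
    n_per_group: int = 16,
    loading_range: tuple[float, float] = (0.6, 0.95),
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[dict[tuple[str, str], ExpressionMatrix], pd.Series]:
    """Four-group design where one module decouples from a correlated block
    at the later age.

    Every module's driver is rho * shared + sqrt(1-rho^2) * own within each
    group, with rho = ``block_rho``, so the modules form one meta-module of
    highly correlated eigengenes — except ``decoupled_module``, whose rho
    drops to ``decoupled_rho`` in the P14 groups (both genotypes),
    emulating a module that leaves the meta-module as the tissue matures
    while mutant/control networks stay alike within each age.

    Returns ({(age, genotype): matrix}, true module labels).
    """
    if not (1 <= decoupled_module <= n_modules):
        raise ValueError("decoupled_module must be one of the modules")
    rng = np.random.default_rng(seed)
    n_genes = n_modules * module_size + n_background
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    labels = np.zeros(n_genes, dtype=int)
    lam = np.zeros(n_genes)
    for m in range(n_modules):
        sl = slice(m * module_size, (m + 1) * module_size)
        labels[sl] = m + 1
        lam[sl] = rng.uniform(*loading_range, size=module_size)
    out = {}
    for age in AGES:
        for geno in ("mutant", "control"):
            shared = rng.standard_normal(n_per_group)
            values = np.empty((n_genes, n_per_group))
            for m in range(n_modules):
                sl = slice(m * module_size, (m + 1) * module_size)
                own = rng.standard_normal(n_per_group)
                rho = block_rho
                if m + 1 == decoupled_module and age == "P14":
                    rho = decoupled_rho
                e = rho * shared + np.sqrt(1 - rho**2) * own
                values[sl] = lam[sl][:, None] * e[None, :] + rng.standard_normal(
                    (module_size, n_per_group)
                ) * noise_sd
            values[n_modules * module_size:] = rng.standard_normal(
                (n_background, n_per_group)
            )
            cols = [f"{age}_{geno[:3]}_{i}" for i in range(n_per_group)]
            out[(age, geno)] = ExpressionMatrix(
                pd.DataFrame(values, index=gene_ids, columns=cols)
            )
    return out, pd.Series(labels, index=gene_ids, name="truth_module")


def formula_mass(formula: str) -> float:
    """Monoisotopic mass of an elemental formula like 'C9H17NO4'."""
    import re

    mass = 0.0
    pos = 0
    for m in re.finditer(r"([A-Z][a-z]?)(\d*)", formula):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = m.end()
        el, count = m.group(1), int(m.group(2) or 1)
        if el not in ELEMENT_MASSES:
            raise ValueError(f"unsupported element {el!r} in {formula!r}")
        mass += ELEMENT_MASSES[el] * count
    if pos != len(formula) or mass <= 0:
        raise ValueError(f"cannot parse formula {formula!r}")
    return mass


ACETYLCARNITINE = "C9H17NO4"


def gen_compound_db(n_decoys: int, seed: int = 0) -> list[CompoundRecord]:
    """Compound database: acetylcarnitine plus random plausible decoys.

    Decoy formulas are drawn as CcHhNnOo with element counts in ranges
    typical of small urinary metabolites; masses are computed from the
    monoisotopic element table, so every record is internally consistent.
    """
    if n_decoys < 0:
        raise ValueError("n_decoys must be >= 0")
    rng = np.random.default_rng(seed)
    records = [
        CompoundRecord(
            "acetylcarnitine",
            ACETYLCARNITINE,
            formula_mass(ACETYLCARNITINE),
            frozenset({"fatty acid oxidation"}),
        )
    ]
    seen = {ACETYLCARNITINE}
    while len(records) < n_decoys + 1:
        c = int(rng.integers(4, 20))
        h = int(rng.integers(max(4, c // 2), 2 * c + 3))
        n = int(rng.integers(0, 4))
        o = int(rng.integers(1, 8))
        formula = f"C{c}H{h}" + (f"N{n}" if n else "") + f"O{o}"
        if formula in seen:
            continue
        seen.add(formula)
        k = int(rng.integers(1, 3))
        pw = frozenset(rng.choice(_PATHWAY_VOCAB, size=k, replace=False).tolist())
        records.append(
            CompoundRecord(f"decoy{len(records):03d}", formula, formula_mass(formula), pw)
        )
    return records


def gen_peak_table(
    db: list[CompoundRecord],
    planted: dict[str, tuple[str, str, float]],
    n_noise_features: int = 100,
    n_per_group: tuple[int, int] = (20, 20),
    ppm_jitter_sd: float = 1.0,
    base_intensity: float = 1.0,
    noise_log_sd: float = 0.3,
    mz_range: tuple[float, float] = (60.0, 600.0),
    seed: int = 0,
) -> tuple[PeakTable, SampleMetadata, pd.DataFrame]:
    """Simulate an LC-MS peak table with planted differential compounds.

    ``planted`` maps compound_id -> (adduct name, mode, fold change):
    the feature's m/z is the adduct-transformed monoisotopic mass with
    multiplicative ppm jitter, and its mutant/control group means differ by
    the fold change with log-normal intensity noise.  Noise features get a
    uniform m/z in the scan range and no group difference.

    Returns (peak table, sample metadata, truth table).
    """
    from .metabolomics import ADDUCT_RULES

    rng = np.random.default_rng(seed)
    by_id = {r.compound_id: r for r in db}
    rules = {(r.name, r.mode): r for r in ADDUCT_RULES}

    n_ctrl, n_mut = n_per_group
    sample_ids = [f"U{i:02d}" for i in range(n_ctrl + n_mut)]
    genotype = ["control"] * n_ctrl + ["mutant"] * n_mut
    meta = SampleMetadata(
        pd.DataFrame(
            {
                "genotype": genotype,
                "age": "P14",
                "batch": "B0",
                "split": "test",
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    mut_mask = np.array([g == "mutant" for g in genotype])

    feats, inten, truth = [], [], []
    fid = 0
    for compound_id, (adduct, mode, fc) in planted.items():
        if compound_id not in by_id:
            raise ValueError(f"unknown compound {compound_id!r}")
        if (adduct, mode) not in rules:
            raise ValueError(f"unknown adduct {adduct!r} for mode {mode!r}")
        if fc <= 0:
            raise ValueError("fold_change must be positive")
        rule = rules[(adduct, mode)]
        mz = (by_id[compound_id].monoisotopic_mass + rule.delta) * (
            1.0 + rng.normal(0.0, ppm_jitter_sd) * 1e-6
        )
        mean = np.where(mut_mask, base_intensity * fc, base_intensity)
        y = mean * np.exp(rng.normal(0.0, noise_log_sd, size=len(sample_ids)))
        name = f"F{fid:04d}"
        feats.append({"feature_id": name, "mode": mode, "mz": mz, "rt": float(rng.uniform(0.5, 10.0))})
        inten.append(y)
        truth.append(
            {
                "feature_id": name,
                "truth_compound": compound_id,
                "truth_adduct": adduct,
                "truth_fold_change": fc,
            }
        )
        fid += 1
    for _ in range(n_noise_features):
        mode = "positive" if rng.random() < 0.5 else "negative"
        mz = float(rng.uniform(*mz_range))
        y = base_intensity * np.exp(rng.normal(0.0, noise_log_sd, size=len(sample_ids)))
        name = f"F{fid:04d}"
        feats.append({"feature_id": name, "mode": mode, "mz": mz, "rt": float(rng.uniform(0.5, 10.0))})
        inten.append(y)
        truth.append(
            {"feature_id": name, "truth_compound": "", "truth_adduct": "", "truth_fold_change": 1.0}
        )
        fid += 1

    features = pd.DataFrame(feats).set_index("feature_id")
    intensities = pd.DataFrame(np.asarray(inten), index=features.index, columns=sample_ids)
    truth_df = pd.DataFrame(truth).set_index("feature_id")
    return PeakTable(features, intensities), meta, truth_df


def gen_phenotype(
    n_per_genotype: tuple[int, int] = (20, 20),
    ratio_effect_sd: float = 0.0,
    cystic_effect_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate per-animal phenotype endpoints.

    Body weight, both kidney weights, and cystic/total section areas for
    control and mutant animals; genotype shifts the kidney/(2*body weight)
    ratio and the cystic index by the stated effects in units of the
    control-group standard deviation.
    """
    n_ctrl, n_mut = n_per_genotype
    if min(n_ctrl, n_mut) < 3:
        raise ValueError("need >= 3 animals per genotype")
    rng = np.random.default_rng(seed)
    rows = []
    # control-scale sds chosen to mimic modest litter variation
    ratio_sd, index_sd = 0.002, 0.05
    for i in range(n_ctrl + n_mut):
        mutant = i >= n_ctrl
        bw = float(rng.normal(10.0, 1.0))
        ratio = 0.012 + (ratio_effect_sd * ratio_sd if mutant else 0.0)
        ratio += rng.normal(0.0, ratio_sd)
        ratio = max(ratio, 1e-4)
        total_kw = 2.0 * bw * ratio
        frac = float(np.clip(rng.normal(0.5, 0.05), 0.2, 0.8))
        ci = 0.15 + (cystic_effect_sd * index_sd if mutant else 0.0)
        ci = float(np.clip(ci + rng.normal(0.0, index_sd), 0.0, 1.0))
        total_area = float(rng.normal(100.0, 10.0))
        rows.append(
            {
                "animal_id": f"A{i:03d}",
                "genotype": "mutant" if mutant else "control",
                "body_weight": bw,
                "kidney_weight_1": total_kw * frac,
                "kidney_weight_2": total_kw * (1.0 - frac),
                "cystic_area": ci * total_area,
                "total_area": total_area,
            }
        )
    return pd.DataFrame(rows).set_index("animal_id")
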
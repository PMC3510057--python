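"""Core data containers shared across the pipeline.

The pipeline operates on log2-scale expression matrices (genes x samples)
with optional per-cell detection p-values, per-sample metadata (genotype,
age, batch, test/validation split), co-expression module assignments with
their eigengenes, and metabolomic peak tables.  Containers are thin
dataclasses over pandas objects; all validation happens at construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENOTYPES = ("control", "mutant")
MODES = ("positive", "negative")


def _check_unique(ids, what: str) -> None:
    s = pd.Index(ids)
    if s.has_duplicates:
        dups = sorted(set(s[s.duplicated()]))
        raise ValueError(f"duplicate {what}: {dups}")


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log2 intensities.

    Parameters
    ----------
    values : DataFrame
        Rows indexed by gene id, columns by sample id, log2 intensity.
    detection_p : DataFrame, optional
        Same shape; per-cell detection p-value in [0, 1] (probability the
        probe signal is indistinguishable from array background).
    """

    values: pd.DataFrame
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene ids")
        _check_unique(self.values.columns, "sample ids")
        if self.detection_p is not None:
            if self.detection_p.shape != self.values.shape:
                raise ValueError(
                    f"detection_p shape {self.detection_p.shape} does not match "
                    f"values shape {self.values.shape}"
                )
            self.detection_p = self.detection_p.reindex(
                index=self.values.index, columns=self.values.columns
            )
            dp = self.detection_p.to_numpy()
            if np.isnan(dp).any() or (dp < 0).any() or (dp > 1).any():
                raise ValueError("detection p-values must lie in [0, 1]")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        dp = None if self.detection_p is None else self.detection_p.loc[gene_ids]
        return ExpressionMatrix(self.values.loc[gene_ids], dp)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        dp = None if self.detection_p is None else self.detection_p[sample_ids]
        return ExpressionMatrix(self.values[sample_ids], dp)


@dataclass
class SampleMetadata:
    """Per-sample design table: genotype, age, batch, split, numeric trait.

    ``trait`` is the 0/1 encoding of genotype (control=0, mutant=1) used for
    eigengene-trait correlation.
    """

    table: pd.DataFrame

    REQUIRED = ("genotype", "age", "batch", "split")

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "sample ids")
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        bad = set(self.table["genotype"]) - set(GENOTYPES)
        if bad:
            raise ValueError(f"unknown genotype labels: {sorted(bad)}")
        if "trait" not in self.table.columns:
            self.table = self.table.assign(
                trait=(self.table["genotype"] == "mutant").astype(int)
            )
        if not set(self.table["trait"]) <= {0, 1}:
            raise ValueError("trait must be a 0/1 genotype encoding")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def aligned_to(self, x: ExpressionMatrix) -> "SampleMetadata":
        """Rows reordered to the matrix's samples; errors on missing ones."""
        missing = [s for s in x.sample_ids if s not in self.table.index]
        if missing:
            raise ValueError(f"samples without metadata: {missing}")
        return SampleMetadata(self.table.loc[x.sample_ids])

    def samples_where(self, **conditions) -> list[str]:
        mask = pd.Series(True, index=self.table.index)
        for col, val in conditions.items():
            mask &= self.table[col] == val
        return list(self.table.index[mask])


@dataclass
class ModuleSet:
    """Module assignment plus eigengene summary.

    labels maps gene id -> module id (0 = unassigned/grey); ``eigengenes``
    is a module x sample matrix of unit-variance first principal components;
    ``var_explained`` the per-module fraction of module variance captured.
    """

    labels: pd.Series
    eigengenes: pd.DataFrame
    var_explained: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def __post_init__(self) -> None:
        if 0 in self.eigengenes.index:
            raise ValueError("module 0 (unassigned) must not carry an eigengene")
        bad = self.var_explained[(self.var_explained <= 0) | (self.var_explained > 1)]
        if len(bad):
            raise ValueError(f"var_explained outside (0,1] for modules {list(bad.index)}")

    @property
    def module_ids(self) -> list[int]:
        return [int(m) for m in self.eigengenes.index]

    def genes_in(self, module_id: int) -> list[str]:
        return list(self.labels.index[self.labels == module_id])


@dataclass
class PeakTable:
    """Untargeted LC-MS feature table.

    ``features`` columns: mode ('positive'/'negative'), mz (Th), rt (min);
    ``intensities`` is feature x sample normalized peak area (>= 0).
    """

    features: pd.DataFrame
    intensities: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.features.index, "feature ids")
        if not self.features.index.equals(self.intensities.index):
            raise ValueError("feature table and intensity matrix indices differ")
        bad_mode = set(self.features["mode"]) - set(MODES)
        if bad_mode:
            raise ValueError(f"unknown ionization modes: {sorted(bad_mode)}")
        if (self.features["mz"] <= 0).any():
            raise ValueError("m/z values must be positive")
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("peak areas must be non-negative")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.features.index)

    def subset(self, feature_ids) -> "PeakTable":
        return PeakTable(self.features.loc[feature_ids], self.intensities.loc[feature_ids])


@dataclass(frozen=True)
class CompoundRecord:
    """Compound-database entry: formula, monoisotopic mass (Da), pathways."""

    compound_id: str
    formula: str
    monoisotopic_mass: float
    pathways: frozenset[str] = frozenset()


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric overlap record.

    k = |query ∩ set|, K = |set|, n = |query|, N = |universe|,
    p = upper-tail hypergeometric p, q = BH-adjusted p across tested sets.
    """

    set_id: str
    k: int
    K: int
    n: int
    N: int
    p: float
    q: float = float("nan")

    def __post_init__(self) -> None:
        if self.k > min(self.K, self.n):
            raise ValueError("overlap exceeds set or query size")
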
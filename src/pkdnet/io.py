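"""Readers and writers for the pipeline's tabular artifacts.

Dialects: expression/metadata/module/DE tables are TSV with a header row;
metabolomics peak tables are CSV (mirroring vendor exports); gene and
compound sets use GMT.  Every reader/writer pair round-trips bit-identically
for string and integer fields and to better than 1e-12 for floats.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .datatypes import CompoundRecord, ExpressionMatrix, PeakTable, SampleMetadata

FLOAT_FMT = "%.12g"


def read_expression(path, detection_path=None) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene id, header of sample
    ids), optionally with a matching detection p-value table."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    dup = values.index[values.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate gene ids in {path}: {sorted(set(dup))}")
    detection = None
    if detection_path is not None:
        detection = pd.read_csv(detection_path, sep="\t", index_col=0)
        if detection.shape != values.shape:
            raise ValueError(
                f"detection table shape {detection.shape} does not match "
                f"expression shape {values.shape}"
            )
    return ExpressionMatrix(values, detection)


def write_expression(x: ExpressionMatrix, path, detection_path=None) -> None:
    x.values.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="gene_id")
    if detection_path is not None:
        if x.detection_p is None:
            raise ValueError("matrix carries no detection p-values")
        x.detection_p.to_csv(detection_path, sep="\t", float_format=FLOAT_FMT,
                             index_label="gene_id")


def read_metadata(path) -> SampleMetadata:
    return SampleMetadata(pd.read_csv(path, sep="\t", index_col=0))


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.table.to_csv(path, sep="\t", index_label="sample_id")


def read_sets(path) -> dict[str, list[str]]:
    """Read a GMT file: name, description, then members, tab-separated."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, _desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ValueError(f"{path}:{lineno}: set {name!r} has no members")
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = members
    return sets


def write_sets(sets: dict, path, descriptions: dict | None = None) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([str(name), desc, *map(str, members)]) + "\n")


def read_peak_table(path) -> PeakTable:
    """Read a peak-table CSV: feature_id, mode, mz, rt, then sample columns."""
    tab = pd.read_csv(path, index_col=0)
    meta_cols = ["mode", "mz", "rt"]
    missing = [c for c in meta_cols if c not in tab.columns]
    if missing:
        raise ValueError(f"peak table {path} missing columns {missing}")
    sample_cols = [c for c in tab.columns if c not in meta_cols]
    return PeakTable(tab[meta_cols], tab[sample_cols])


def write_peak_table(pt: PeakTable, path) -> None:
    pd.concat([pt.features, pt.intensities], axis=1).to_csv(
        path, float_format=FLOAT_FMT, index_label="feature_id"
    )


def read_compound_db(path) -> list[CompoundRecord]:
    """Read a compound DB TSV: compound_id, formula, monoisotopic_mass,
    pathways (semicolon-joined)."""
    tab = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False)
    records = []
    for cid, row in tab.iterrows():
        pw = frozenset(p for p in str(row["pathways"]).split(";") if p)
        records.append(
            CompoundRecord(str(cid), str(row["formula"]),
                           float(row["monoisotopic_mass"]), pw)
        )
    return records


def write_compound_db(db: list[CompoundRecord], path) -> None:
    rows = [
        {
            "compound_id": r.compound_id,
            "formula": r.formula,
            "monoisotopic_mass": r.monoisotopic_mass,
            "pathways": ";".join(sorted(r.pathways)),
        }
        for r in db
    ]
    pd.DataFrame(rows).set_index("compound_id").to_csv(
        path, sep="\t", float_format=FLOAT_FMT
    )


def read_table(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, **kw)


def write_table(tab: pd.DataFrame, path, index_label=None) -> None:
    tab.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label=index_label)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
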
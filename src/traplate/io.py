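"""Tab-separated readers and writers for all pipeline tables.

The canonical on-disk dialect is UTF-8 TSV with a header row; gene
identifiers occupy the first column of expression matrices. Missing
values are not permitted: absence of a gene is absence of a row.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    MarkerSet,
    ParseError,
    SampleSheet,
    ValidationError,
    validate_marker_collection,
)


def read_expression_matrix(path: str | os.PathLike, format: str = "tsv") -> ExpressionMatrix:
    """Read a genes x samples TPM matrix from TSV.

    The first column holds gene identifiers; remaining columns are one
    per sample, named in the header row. Duplicate gene identifiers,
    missing cells, negative or non-numeric values are all rejected with
    an error naming the offending coordinates.
    """
    if format != "tsv":
        raise ValueError(f"unsupported format {format!r}")
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if raw.shape[1] < 2:
        raise ParseError(f"{path}: expected gene-id column plus >= 1 sample column")
    gene_col = raw.columns[0]
    genes = raw[gene_col]
    dup = genes[genes.duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate gene_id: {dup.iloc[0]!r}")
    values = raw.drop(columns=[gene_col])
    numeric = values.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric or missing value {values.iloc[r, c]!r} "
            f"at gene {genes.iloc[r]!r}, sample {values.columns[c]!r}"
        )
    neg = numeric.to_numpy() < 0
    if neg.any():
        r, c = np.argwhere(neg)[0]
        raise ParseError(
            f"{path}: negative value at gene {genes.iloc[r]!r}, "
            f"sample {values.columns[c]!r}"
        )
    numeric.index = pd.Index(genes, name="gene_id")
    return ExpressionMatrix(numeric)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | os.PathLike) -> None:
    df = matrix.data.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_sample_sheet(path: str | os.PathLike) -> SampleSheet:
    """Read the sample sheet (columns sample_id, fraction, group, replicate)."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "fraction": str, "group": str})
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: sample sheet file is empty") from None
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | os.PathLike) -> None:
    sheet.records.to_csv(path, sep="\t", index=False)


def read_marker_sets(path: str | os.PathLike) -> list[MarkerSet]:
    """Read marker sets from a two-column TSV (set_name, gene_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["set_name", "gene_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: marker file missing columns {missing}")
    sets = []
    for name, sub in df.groupby("set_name", sort=False):
        sets.append(MarkerSet(name=str(name), genes=tuple(sub["gene_id"])))
    validate_marker_collection(sets)
    return sets


def write_marker_sets(markers: Iterable[MarkerSet], path: str | os.PathLike) -> None:
    rows = [(m.name, g) for m in markers for g in m.genes]
    pd.DataFrame(rows, columns=["set_name", "gene_id"]).to_csv(path, sep="\t", index=False)


DE_TABLE_COLUMNS = [
    "gene_id",
    "median_control",
    "median_condition",
    "log2fc",
    "ssmd",
    "bc_mod",
    "call",
]


def write_de_table(results, path: str | os.PathLike) -> None:
    """Serialize DE results (the dual-flashlight table) sorted by gene_id.

    Numeric columns are printed to 6 significant digits.
    """
    rows = [
        (
            r.gene_id,
            r.median_control,
            r.median_condition,
            r.log2fc,
            r.ssmd,
            r.bc_mod,
            r.call,
        )
        for r in sorted(results, key=lambda r: r.gene_id)
    ]
    df = pd.DataFrame(rows, columns=DE_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_de_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "call": str})
    missing = [c for c in DE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: DE table missing columns {missing}")
    return df


def write_gene_list(genes: Iterable[str], path: str | os.PathLike) -> None:
    """One gene identifier per line, sorted for deterministic output."""
    with open(path, "w", encoding="utf-8") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


def read_gene_list(path: str | os.PathLike) -> set[str]:
    with open(path, encoding="utf-8") as fh:
        return {line.strip() for line in fh if line.strip()}
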
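"""Core in-memory containers for TRAP-Seq expression data.

The pipeline operates on gene-by-sample TPM matrices together with a
sample sheet assigning each library to a fraction (IN = input
transcriptome, IP = immunoprecipitated translatome) and an experimental
group (control vs condition), plus named marker gene sets used for the
cell-type specificity QC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

FRACTIONS = ("IN", "IP")
GROUPS = ("control", "condition")


class ValidationError(ValueError):
    """Raised when an input object violates a structural invariant."""


class ParseError(ValueError):
    """Raised when a file cannot be parsed into a valid object."""


def _check_unique(labels, what: str) -> None:
    seen = set()
    for lab in labels:
        if lab in seen:
            raise ValidationError(f"duplicate {what}: {lab!r}")
        seen.add(lab)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Dense genes x samples matrix of TPM values.

    ``data`` holds genes on the index and samples on the columns. All
    entries must be finite and non-negative; gene and sample identifiers
    must be unique. Gene identifiers are opaque strings — marker sets and
    sample sheets must live in the same identifier space.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(df.index, "gene_id")
        _check_unique(df.columns, "sample_id")
        values = df.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if values.size:
            if not np.isfinite(values).all():
                bad = np.argwhere(~np.isfinite(values))[0]
                raise ValidationError(
                    f"non-finite value at gene {df.index[bad[0]]!r}, "
                    f"sample {df.columns[bad[1]]!r}"
                )
            if (values < 0).any():
                bad = np.argwhere(values < 0)[0]
                raise ValidationError(
                    f"negative value at gene {df.index[bad[0]]!r}, "
                    f"sample {df.columns[bad[1]]!r}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        """Restrict to ``genes`` (kept in current matrix order)."""
        genes = set(genes)
        missing = genes - set(self.data.index)
        if missing:
            raise ValidationError(f"unknown gene ids: {sorted(missing)[:5]}")
        keep = [g for g in self.data.index if g in genes]
        return ExpressionMatrix(self.data.loc[keep])

    def subset_samples(self, samples) -> "ExpressionMatrix":
        missing = set(samples) - set(self.data.columns)
        if missing:
            raise ValidationError(f"unknown sample ids: {sorted(missing)[:5]}")
        return ExpressionMatrix(self.data.loc[:, list(samples)])


@dataclass(frozen=True)
class SampleSheet:
    """Sample annotations: one record per library.

    Columns: ``sample_id``, ``fraction`` (IN/IP), ``group``
    (control/condition), ``replicate`` (positive integer).
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        required = ["sample_id", "fraction", "group", "replicate"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns: {missing}")
        if len(df) == 0:
            raise ValidationError("sample sheet is empty")
        _check_unique(df["sample_id"], "sample_id")
        bad_frac = sorted(set(df["fraction"]) - set(FRACTIONS))
        if bad_frac:
            raise ValidationError(
                f"unknown fraction value(s) {bad_frac}; allowed: {list(FRACTIONS)}"
            )
        bad_grp = sorted(set(df["group"]) - set(GROUPS))
        if bad_grp:
            raise ValidationError(
                f"unknown group value(s) {bad_grp}; allowed: {list(GROUPS)}"
            )
        reps = pd.to_numeric(df["replicate"], errors="coerce")
        if reps.isna().any() or (reps < 1).any() or (reps != reps.astype(int)).any():
            raise ValidationError("replicate must be a positive integer")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.records["sample_id"])

    def samples_for(self, fraction: str | None = None, group: str | None = None) -> list[str]:
        """Sample ids matching the given fraction and/or group, sheet order."""
        df = self.records
        if fraction is not None:
            if fraction not in FRACTIONS:
                raise ValidationError(f"unknown fraction {fraction!r}")
            df = df[df["fraction"] == fraction]
        if group is not None:
            if group not in GROUPS:
                raise ValidationError(f"unknown group {group!r}")
            df = df[df["group"] == group]
        return list(df["sample_id"])

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        """Require a one-to-one match between sheet and matrix samples."""
        sheet = set(self.sample_ids)
        mat = set(matrix.sample_ids)
        only_sheet = sorted(sheet - mat)
        only_mat = sorted(mat - sheet)
        if only_sheet or only_mat:
            raise ValidationError(
                "sample sheet / matrix mismatch: "
                f"in sheet only {only_sheet}, in matrix only {only_mat}"
            )

    def require_replicates(self, minimum: int = 2) -> None:
        """Every present (fraction, group) cell must have >= ``minimum`` replicates."""
        counts = self.records.groupby(["fraction", "group"]).size()
        low = counts[counts < minimum]
        if len(low):
            raise ValidationError(
                f"need >= {minimum} replicates per (fraction, group); got {dict(low)}"
            )


@dataclass(frozen=True)
class MarkerSet:
    """A named cell-type marker gene set (e.g. microglial markers)."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"marker set {self.name!r} is empty")
        _check_unique(self.genes, f"gene in marker set {self.name!r}")


def validate_marker_collection(markers: list[MarkerSet]) -> None:
    _check_unique((m.name for m in markers), "marker set name")
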
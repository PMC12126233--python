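"""Specificity and reproducibility QC for TRAP fractions.

Two checks: (i) pairwise Pearson correlation of log-expression between
samples — biological replicates of the same fraction and group should
correlate at r >= 0.97; (ii) enrichment of cell-type marker genes in the
immunoprecipitated (IP) fraction relative to the input (IN) — markers of
the targeted cell type (microglia) must be enriched, markers of other
cell types depleted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    MarkerSet,
    SampleSheet,
    ValidationError,
    validate_marker_collection,
)

#: default marker genes for the three cell-type sets (mouse symbols)
DEFAULT_MARKER_SETS = (
    MarkerSet("microglial", ("Tmem119", "Aif1", "Cx3cr1", "P2ry12")),
    MarkerSet("neuronal", ("Gad2", "Camk2a", "Calca", "Calcb")),
    MarkerSet("other_nonneuronal", ("Sox10", "Olig1", "Gfap", "Mog", "Mbp", "Olig2")),
)


@dataclass
class QCReport:
    """Replicate-correlation and marker-enrichment results.

    ``correlations`` is the symmetric sample-by-sample Pearson matrix;
    ``min_within_group_r`` the smallest correlation among replicate
    pairs of the same (fraction, group); ``marker_table`` one row per
    marker gene found in the matrix with its IP/IN log2 enrichment;
    ``set_enrichment`` the per-set median of those log2 enrichments.
    """

    correlations: pd.DataFrame | None = None
    min_within_group_r: float | None = None
    worst_pair: tuple[str, str] | None = None
    within_group_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    marker_table: pd.DataFrame | None = None
    set_enrichment: dict[str, float] = field(default_factory=dict)


def replicate_correlation(
    matrix: ExpressionMatrix,
    gene_universe,
    log_transform: bool = True,
    sheet: SampleSheet | None = None,
    report: QCReport | None = None,
) -> QCReport:
    """Pairwise Pearson r between samples on log2(TPM + 1).

    Restricted to ``gene_universe``. When a sample sheet is supplied the
    report additionally carries every within-(fraction, group) replicate
    pair with its correlation, and the minimum over those pairs.
    """
    sub = matrix.subset_genes(gene_universe)
    if sub.n_samples < 2:
        raise ValidationError("replicate correlation requires >= 2 samples")
    values = sub.values.astype(float)
    if log_transform:
        values = np.log2(values + 1.0)
    sds = values.std(axis=0)
    for j, sd in enumerate(sds):
        if sd == 0:
            raise ValidationError(
                f"sample {sub.sample_ids[j]!r} has zero variance; correlation undefined"
            )
    corr = np.corrcoef(values, rowvar=False)
    corr_df = pd.DataFrame(corr, index=sub.sample_ids, columns=sub.sample_ids)

    report = report or QCReport()
    report.correlations = corr_df
    if sheet is not None:
        sheet.validate_against(matrix)
        pairs: list[tuple[str, str, float]] = []
        for (_, _), cell in sheet.records.groupby(["fraction", "group"]):
            ids = list(cell["sample_id"])
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    pairs.append((ids[i], ids[j], float(corr_df.loc[ids[i], ids[j]])))
        report.within_group_pairs = pairs
        if pairs:
            worst = min(pairs, key=lambda p: p[2])
            report.min_within_group_r = worst[2]
            report.worst_pair = (worst[0], worst[1])
    return report


def marker_enrichment(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    markers=DEFAULT_MARKER_SETS,
    pseudocount: float = 0.01,
    report: QCReport | None = None,
) -> QCReport:
    """IP-over-IN log2 enrichment of each marker gene, and set medians.

    Per gene: ``log2((median over IP samples + pc)/(median over IN
    samples + pc))``; per set, the median over its genes present in the
    matrix. Raises if none of a collection's genes are found.
    """
    markers = list(markers)
    validate_marker_collection(markers)
    sheet.validate_against(matrix)
    ip = sheet.samples_for(fraction="IP")
    in_ = sheet.samples_for(fraction="IN")
    if not ip or not in_:
        raise ValidationError("marker enrichment needs both IP and IN samples")

    present = set(matrix.gene_ids)
    all_genes = [g for m in markers for g in m.genes]
    found = [g for g in all_genes if g in present]
    if not found:
        raise ValidationError(f"no marker genes found in matrix; missing: {sorted(all_genes)}")

    rows = []
    set_enrichment: dict[str, float] = {}
    for m in markers:
        per_gene = []
        for g in m.genes:
            if g not in present:
                continue
            ip_med = float(matrix.data.loc[g, ip].median())
            in_med = float(matrix.data.loc[g, in_].median())
            enr = math.log2((ip_med + pseudocount) / (in_med + pseudocount))
            per_gene.append(enr)
            rows.append((g, m.name, ip_med, in_med, enr))
        if per_gene:
            set_enrichment[m.name] = float(np.median(per_gene))

    report = report or QCReport()
    report.marker_table = pd.DataFrame(
        rows, columns=["gene_id", "set_name", "ip_median", "in_median", "log2_enrichment"]
    )
    report.set_enrichment = set_enrichment
    return report


def qc_gate(
    report: QCReport,
    min_replicate_r: float = 0.97,
    require_marker_sign: bool = True,
) -> tuple[bool, list[str]]:
    """Pass/fail decision over a completed QC report.

    Fails when any within-group replicate correlation drops below
    ``min_replicate_r``, or (when ``require_marker_sign``) when the
    microglial set-level enrichment is not positive or any other set's
    is not negative. Returns ``(passed, reasons)`` with one reason per
    violation; never raises.
    """
    reasons: list[str] = []
    for a, b, r in report.within_group_pairs:
        if r < min_replicate_r:
            reasons.append(
                f"replicate pair ({a}, {b}) correlation r={r:.4f} below {min_replicate_r}"
            )
    if require_marker_sign:
        for name, enr in report.set_enrichment.items():
            if name == "microglial" and enr <= 0:
                reasons.append(f"microglial marker set not enriched in IP (median log2 {enr:.3f})")
            if name != "microglial" and enr >= 0:
                reasons.append(
                    f"non-microglial marker set {name!r} not depleted in IP "
                    f"(median log2 {enr:.3f})"
                )
    return (not reasons, reasons)


def write_qc_report(report: QCReport, corr_path, marker_path) -> None:
    """Write the correlation matrix and marker table as TSV."""
    if report.correlations is not None:
        df = report.correlations.copy()
        df.index.name = "sample_id"
        df.to_csv(corr_path, sep="\t", float_format="%.6g")
    if report.marker_table is not None:
        report.marker_table.to_csv(marker_path, sep="\t", index=False, float_format="%.6g")
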
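"""Differential ribosome-occupancy statistics.

Differential expression between the two groups is called per gene from
three complementary statistics, with no p-values:

* **log2 fold change** on group medians of (quantile-normalized) TPM,
  oriented condition-over-control;
* **SSMD** (strictly standardized mean difference),
  ``(mean_condition - mean_control) / sqrt(var_condition + var_control)``,
  computed on percentile ranks so it captures systematic shifts in a
  gene's position within each sample's expression distribution;
* a **signed Bhattacharyya overlap**: a normal distribution is fitted to
  each group's TPM values, the classical Bhattacharyya coefficient
  ``BC = exp(-D_B)`` measures their overlap (1 = identical), and the
  reported statistic is ``sign(log2FC) * (1 - BC)`` so that 0 means
  identical distributions and +/-1 totally disjoint ones.

A gene is called *increased* when SSMD >= 0.9, the signed overlap
statistic >= 0.5, and the linear fold change >= 1.33 with positive
log2FC; *decreased* under the sign-mirrored conditions; otherwise
*unchanged*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, SampleSheet, ValidationError
from .ranknorm import FilterThresholds, define_gene_universes, percentile_rank, quantile_normalize

#: sentinel magnitude for SSMD when both groups are exactly constant
#: but their means differ (zero denominator)
SSMD_SENTINEL = 1e9

#: variance floor used when fitting per-group normals for the overlap
#: statistic; keeps the Bhattacharyya distance finite on constant groups
BC_VARIANCE_FLOOR = 1e-8

DEFAULT_PSEUDOCOUNT = 0.01


@dataclass(frozen=True)
class DEThresholds:
    """The triple threshold for calling differential occupancy."""

    ssmd_min: float = 0.9
    bc_min: float = 0.5
    fc_min: float = 1.33

    def __post_init__(self) -> None:
        if self.ssmd_min <= 0:
            raise ValidationError("ssmd_min must be > 0")
        if not 0 < self.bc_min <= 1:
            raise ValidationError("bc_min must be in (0, 1]")
        if self.fc_min < 1:
            raise ValidationError("fc_min must be >= 1")


@dataclass(frozen=True)
class GeneGroupSummary:
    """Per-gene inputs to the three statistics.

    ``group_values_*`` are normalized TPM (one entry per replicate);
    ``rank_values_*`` are the matching percentile ranks.
    """

    gene_id: str
    group_values_control: tuple[float, ...]
    group_values_condition: tuple[float, ...]
    rank_values_control: tuple[float, ...]
    rank_values_condition: tuple[float, ...]

    def __post_init__(self) -> None:
        for name in (
            "group_values_control",
            "group_values_condition",
            "rank_values_control",
            "rank_values_condition",
        ):
            vals = getattr(self, name)
            if len(vals) < 2:
                raise ValidationError(f"{self.gene_id}: {name} needs >= 2 replicates")
            if not all(math.isfinite(v) for v in vals):
                raise ValidationError(f"{self.gene_id}: non-finite value in {name}")


@dataclass(frozen=True)
class DEResult:
    """One row of the dual-flashlight table."""

    gene_id: str
    median_control: float
    median_condition: float
    log2fc: float
    ssmd: float
    bc_mod: float
    call: str  # increased | decreased | unchanged


def log2_fold_change(control, condition, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    """log2 of (median(condition) + pc) / (median(control) + pc)."""
    control = np.asarray(control, dtype=float)
    condition = np.asarray(condition, dtype=float)
    if control.size == 0 or condition.size == 0:
        raise ValidationError("empty group in fold-change computation")
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    mc = float(np.median(control))
    mt = float(np.median(condition))
    if pseudocount == 0 and (mc == 0 or mt == 0):
        raise ValidationError("zero median with zero pseudocount: fold change undefined")
    return math.log2((mt + pseudocount) / (mc + pseudocount))


def ssmd(control, condition) -> float:
    """Strictly standardized mean difference, condition minus control.

    Uses unbiased (n-1) variances. When both groups are exactly
    constant the result is 0 for equal means and a +/-1e9 sentinel
    otherwise.
    """
    control = np.asarray(control, dtype=float)
    condition = np.asarray(condition, dtype=float)
    if control.size < 2 or condition.size < 2:
        raise ValidationError("SSMD requires >= 2 replicates per group")
    diff = condition.mean() - control.mean()
    denom = control.var(ddof=1) + condition.var(ddof=1)
    if denom == 0:
        if diff == 0:
            return 0.0
        return math.copysign(SSMD_SENTINEL, diff)
    return float(diff / math.sqrt(denom))


def bhattacharyya_modified(control, condition, sign_source: float) -> float:
    """Signed distribution-overlap statistic in [-1, 1].

    Fits ``Normal(mean, var)`` to each group (unbiased variances floored
    at 1e-8), evaluates the Gaussian closed-form Bhattacharyya distance

    ``D_B = 1/4 ln(1/4 (s2c/s2t + s2t/s2c + 2)) + 1/4 (mc - mt)^2 / (s2c + s2t)``

    and returns ``sign(sign_source) * (1 - exp(-D_B))``: 0 for identical
    distributions, approaching +/-1 for disjoint ones. Returns 0.0 when
    ``sign_source`` is 0.
    """
    control = np.asarray(control, dtype=float)
    condition = np.asarray(condition, dtype=float)
    if control.size < 2 or condition.size < 2:
        raise ValidationError("Bhattacharyya overlap requires >= 2 replicates per group")
    s2c = max(control.var(ddof=1), BC_VARIANCE_FLOOR)
    s2t = max(condition.var(ddof=1), BC_VARIANCE_FLOOR)
    mc = control.mean()
    mt = condition.mean()
    db = 0.25 * math.log(0.25 * (s2c / s2t + s2t / s2c + 2.0)) + 0.25 * (mc - mt) ** 2 / (
        s2c + s2t
    )
    bc = math.exp(-db)
    if sign_source == 0:
        return 0.0
    return math.copysign(1.0 - bc, sign_source)


def translational_efficiency(ip_values, in_values, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    """IP/IN median ratio — the proxy for a gene's translational status."""
    ip_values = np.asarray(ip_values, dtype=float)
    in_values = np.asarray(in_values, dtype=float)
    if ip_values.size == 0 or in_values.size == 0:
        raise ValidationError("empty group in translational-efficiency computation")
    m_in = float(np.median(in_values))
    if pseudocount == 0 and m_in == 0:
        raise ValidationError("zero IN median with zero pseudocount: ratio undefined")
    return (float(np.median(ip_values)) + pseudocount) / (m_in + pseudocount)


def _classify(log2fc: float, ssmd_value: float, bc_value: float, thresholds: DEThresholds) -> str:
    fc_ratio = 2.0 ** log2fc
    if (
        log2fc > 0
        and ssmd_value >= thresholds.ssmd_min
        and bc_value >= thresholds.bc_min
        and fc_ratio >= thresholds.fc_min
    ):
        return "increased"
    if (
        log2fc < 0
        and ssmd_value <= -thresholds.ssmd_min
        and bc_value <= -thresholds.bc_min
        and fc_ratio <= 1.0 / thresholds.fc_min
    ):
        return "decreased"
    return "unchanged"


def call_de(
    summary: GeneGroupSummary,
    thresholds: DEThresholds = DEThresholds(),
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> DEResult:
    """Apply the triple-threshold rule to one gene.

    log2FC and the signed overlap come from the normalized TPM values;
    SSMD comes from the percentile ranks. The overlap statistic takes
    its sign from the log2 fold change.
    """
    lfc = log2_fold_change(summary.group_values_control, summary.group_values_condition, pseudocount)
    s = ssmd(summary.rank_values_control, summary.rank_values_condition)
    bc = bhattacharyya_modified(
        summary.group_values_control, summary.group_values_condition, sign_source=lfc
    )
    return DEResult(
        gene_id=summary.gene_id,
        median_control=float(np.median(summary.group_values_control)),
        median_condition=float(np.median(summary.group_values_condition)),
        log2fc=lfc,
        ssmd=s,
        bc_mod=bc,
        call=_classify(lfc, s, bc, thresholds),
    )


def _group_arrays(matrix: ExpressionMatrix, samples: list[str]) -> np.ndarray:
    return matrix.data[samples].to_numpy(dtype=float)


def run_de_analysis(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    thresholds: DEThresholds = DEThresholds(),
    fraction: str = "IP",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    filter_thresholds: FilterThresholds = FilterThresholds(),
) -> list[DEResult]:
    """Full per-gene DE analysis of one fraction from a raw TPM matrix.

    Defines the expressed-gene universes, quantile-normalizes the chosen
    fraction's samples over the transcriptome universe, computes
    percentile ranks of the normalized values within the analysis
    universe (translatome genes for IP, transcriptome genes for IN),
    and emits one :class:`DEResult` per gene in that universe. The
    computation is vectorized across genes but numerically identical to
    calling :func:`call_de` gene by gene.
    """
    if fraction not in ("IP", "IN"):
        raise ValidationError(f"fraction must be IP or IN, got {fraction!r}")
    sheet.validate_against(matrix)
    sheet.require_replicates(2)
    transcriptome, translatome = define_gene_universes(matrix, sheet, filter_thresholds)
    universe = translatome if fraction == "IP" else transcriptome
    if not universe:
        return []

    frac_samples = sheet.samples_for(fraction=fraction)
    ctrl = sheet.samples_for(fraction=fraction, group="control")
    cond = sheet.samples_for(fraction=fraction, group="condition")
    if len(ctrl) < 2 or len(cond) < 2:
        raise ValidationError(
            f"fraction {fraction}: need >= 2 replicates in each group "
            f"(control: {len(ctrl)}, condition: {len(cond)})"
        )

    norm = quantile_normalize(matrix.subset_samples(frac_samples), transcriptome)
    analysis = norm.subset_genes(universe)
    ranks = percentile_rank(analysis)

    genes = analysis.gene_ids
    vc = _group_arrays(analysis, ctrl)
    vt = _group_arrays(analysis, cond)
    rc = ranks.data[ctrl].to_numpy(dtype=float)
    rt = ranks.data[cond].to_numpy(dtype=float)

    med_c = np.median(vc, axis=1)
    med_t = np.median(vt, axis=1)
    lfc = np.log2((med_t + pseudocount) / (med_c + pseudocount))

    diff = rt.mean(axis=1) - rc.mean(axis=1)
    denom = rc.var(axis=1, ddof=1) + rt.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ssmd_vals = diff / np.sqrt(denom)
    degenerate = denom == 0
    ssmd_vals[degenerate] = np.sign(diff[degenerate]) * SSMD_SENTINEL

    s2c = np.maximum(vc.var(axis=1, ddof=1), BC_VARIANCE_FLOOR)
    s2t = np.maximum(vt.var(axis=1, ddof=1), BC_VARIANCE_FLOOR)
    db = 0.25 * np.log(0.25 * (s2c / s2t + s2t / s2c + 2.0)) + 0.25 * (
        vc.mean(axis=1) - vt.mean(axis=1)
    ) ** 2 / (s2c + s2t)
    bc_vals = np.sign(lfc) * (1.0 - np.exp(-db))

    results = []
    for i, g in enumerate(genes):
        results.append(
            DEResult(
                gene_id=g,
                median_control=float(med_c[i]),
                median_condition=float(med_t[i]),
                log2fc=float(lfc[i]),
                ssmd=float(ssmd_vals[i]),
                bc_mod=float(bc_vals[i]),
                call=_classify(float(lfc[i]), float(ssmd_vals[i]), float(bc_vals[i]), thresholds),
            )
        )
    return results


def de_results_frame(results: list[DEResult]) -> pd.DataFrame:
    """DE results as a DataFrame indexed by gene_id (sorted)."""
    rows = {
        r.gene_id: (r.median_control, r.median_condition, r.log2fc, r.ssmd, r.bc_mod, r.call)
        for r in results
    }
    df = pd.DataFrame.from_dict(
        rows,
        orient="index",
        columns=["median_control", "median_condition", "log2fc", "ssmd", "bc_mod", "call"],
    )
    df.index.name = "gene_id"
    return df.sort_index()
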
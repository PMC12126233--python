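"""Percentile ranks, consistency filtering, and quantile normalization.

The expressed-gene universes are defined in two nested stages. First,
genes above a percentile threshold (default 30) in *every* input (IN)
sample form the transcriptome universe — the consistently transcribed
coding genes. Percentile ranks are then recomputed within that universe
for each immunoprecipitated (IP) sample, and genes at or above a second
threshold (default 15) in every IP sample form the translatome universe.
The IN-stage filter is strict (rank > threshold), the IP stage inclusive
(rank >= threshold); the translatome is always a subset of the
transcriptome.

Percentile ranks use midranks for ties, scaled as ``100 * (r - 1) / (N - 1)``
so the least-expressed gene in a sample sits at 0 and the most expressed
at 100. Ranks depend only on the ordering of values, never their scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import ExpressionMatrix, SampleSheet, ValidationError


@dataclass(frozen=True)
class RankMatrix:
    """Per-sample percentile ranks of genes, values in [0, 100]."""

    data: pd.DataFrame

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass(frozen=True)
class FilterThresholds:
    """Percentile cutoffs for the two consistency-filter stages."""

    transcriptome_percentile: float = 30.0
    translatome_percentile: float = 15.0

    def __post_init__(self) -> None:
        for v in (self.transcriptome_percentile, self.translatome_percentile):
            if not 0 <= v <= 100:
                raise ValidationError(f"percentile threshold {v} outside [0, 100]")


def percentile_rank(matrix: ExpressionMatrix) -> RankMatrix:
    """Percentile-rank every gene within each sample independently.

    Gene *i* receives ``100 * (r_i - 1) / (N - 1)`` where ``r_i`` is its
    1-based midrank among the sample's values in ascending order.
    """
    n = matrix.n_genes
    if n < 2:
        raise ValidationError("percentile ranks require >= 2 genes")
    values = matrix.values
    ranks = np.empty_like(values, dtype=float)
    for j in range(values.shape[1]):
        r = rankdata(values[:, j], method="average")
        ranks[:, j] = 100.0 * (r - 1.0) / (n - 1.0)
    return RankMatrix(pd.DataFrame(ranks, index=matrix.data.index, columns=matrix.data.columns))


def filter_consistently_expressed(
    ranks: RankMatrix,
    samples,
    percentile: float,
    inclusive: bool,
) -> set[str]:
    """Genes whose rank clears ``percentile`` in every listed sample.

    ``inclusive=True`` keeps genes at rank == percentile ("at or above");
    ``inclusive=False`` requires strictly greater ("above").
    """
    samples = list(samples)
    if not samples:
        raise ValidationError("no samples given to consistency filter")
    missing = set(samples) - set(ranks.data.columns)
    if missing:
        raise ValidationError(f"unknown sample ids: {sorted(missing)}")
    sub = ranks.data[samples].to_numpy()
    keep = (sub >= percentile) if inclusive else (sub > percentile)
    mask = keep.all(axis=1)
    return set(ranks.data.index[mask])


def quantile_normalize(matrix: ExpressionMatrix, gene_universe) -> ExpressionMatrix:
    """Force every sample to share the identical value distribution.

    Restricted to ``gene_universe``, each sample's sorted values are
    replaced by the position-wise mean of sorted values across samples;
    within-sample ties receive the mean of the reference values their
    positions span. Genes outside the universe are dropped.
    """
    if matrix.n_samples < 2:
        raise ValidationError("quantile normalization requires >= 2 samples")
    sub = matrix.subset_genes(gene_universe)
    values = sub.values.astype(float)
    n = values.shape[0]
    if n == 0:
        raise ValidationError("gene universe is empty")
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        col_sorted = col[order]
        # tied values share the mean of the reference entries their
        # sorted positions span
        run_start = np.empty(n, dtype=bool)
        run_start[0] = True
        run_start[1:] = col_sorted[1:] != col_sorted[:-1]
        starts = np.flatnonzero(run_start)
        run_sums = np.add.reduceat(reference, starts)
        run_lens = np.diff(np.append(starts, n))
        run_means = run_sums / run_lens
        mapped_sorted = run_means[np.cumsum(run_start) - 1]
        out[order, j] = mapped_sorted
    return ExpressionMatrix(pd.DataFrame(out, index=sub.data.index, columns=sub.data.columns))


def define_gene_universes(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    thresholds: FilterThresholds = FilterThresholds(),
) -> tuple[set[str], set[str]]:
    """Nested transcriptome / translatome expressed-gene universes.

    Returns ``(transcriptome_set, translatome_set)``. The transcriptome
    stage applies the strict filter over all IN samples on ranks computed
    over the full gene list; the translatome stage recomputes IP-sample
    ranks *within* the transcriptome universe and applies the inclusive
    filter.
    """
    sheet.validate_against(matrix)
    in_samples = sheet.samples_for(fraction="IN")
    ip_samples = sheet.samples_for(fraction="IP")
    if not in_samples:
        raise ValidationError("no IN samples in sheet")
    if not ip_samples:
        raise ValidationError("no IP samples in sheet")

    ranks_all = percentile_rank(matrix)
    transcriptome = filter_consistently_expressed(
        ranks_all, in_samples, thresholds.transcriptome_percentile, inclusive=False
    )
    if not transcriptome:
        return set(), set()
    ip_matrix = matrix.subset_genes(transcriptome).subset_samples(ip_samples)
    ranks_ip = percentile_rank(ip_matrix)
    translatome = filter_consistently_expressed(
        ranks_ip, ip_samples, thresholds.translatome_percentile, inclusive=True
    )
    return transcriptome, translatome
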
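"""End-to-end orchestration: filter -> normalize -> DE -> QC.

A run consumes a TPM matrix, a sample sheet, and (optionally) marker
sets, and writes gene-universe lists, normalized matrices, the DE
table, QC tables, and a JSON manifest summarizing the run. Reruns on
identical inputs reproduce identical tables; the manifest additionally
records a wall-clock timestamp.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .containers import ExpressionMatrix, MarkerSet, SampleSheet, ValidationError
from .destats import DEThresholds, de_results_frame, run_de_analysis
from .io import (
    read_expression_matrix,
    read_marker_sets,
    read_sample_sheet,
    write_de_table,
    write_expression_matrix,
    write_gene_list,
)
from .qc import (
    DEFAULT_MARKER_SETS,
    QCReport,
    marker_enrichment,
    qc_gate,
    replicate_correlation,
    write_qc_report,
)
from .ranknorm import FilterThresholds, define_gene_universes, quantile_normalize

log = logging.getLogger("traplate")


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved configuration of one pipeline run."""

    matrix_path: str
    samples_path: str
    out_dir: str
    markers_path: str | None = None
    filter_thresholds: FilterThresholds = FilterThresholds()
    de_thresholds: DEThresholds = DEThresholds()
    pseudocount: float = 0.01
    min_replicate_r: float = 0.97
    require_marker_sign: bool = True
    analyze_in_fraction: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        ft = kwargs.pop("filter_thresholds", None)
        if isinstance(ft, dict):
            kwargs["filter_thresholds"] = FilterThresholds(**ft)
        dt = kwargs.pop("de_thresholds", None)
        if isinstance(dt, dict):
            kwargs["de_thresholds"] = DEThresholds(**dt)
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def validate_paths(self) -> None:
        for p in (self.matrix_path, self.samples_path, self.markers_path):
            if p is not None and not Path(p).is_file():
                raise ValidationError(f"input file not found: {p}")


@dataclass
class RunManifest:
    """Headline numbers and provenance of one run."""

    config: dict
    n_genes_input: int = 0
    n_transcriptome: int = 0
    n_translatome: int = 0
    n_increased: int = 0
    n_decreased: int = 0
    n_unchanged: int = 0
    qc_passed: bool | None = None
    qc_reasons: list[str] = field(default_factory=list)
    min_within_group_r: float | None = None
    marker_set_enrichment: dict[str, float] = field(default_factory=dict)
    version: str = __version__
    timestamp: str = ""

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(
    config: RunConfig,
    matrix: ExpressionMatrix | None = None,
    sheet: SampleSheet | None = None,
    markers: list[MarkerSet] | None = None,
) -> RunManifest:
    """Execute the full analysis and write all outputs under ``out_dir``.

    ``matrix``/``sheet``/``markers`` may be passed in memory; otherwise
    they are read from the configured paths.
    """
    t0 = time.monotonic()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out / "run.log")

    if matrix is None or sheet is None:
        config.validate_paths()
        log.info("stage=load reading matrix %s", config.matrix_path)
        matrix = read_expression_matrix(config.matrix_path)
        sheet = read_sample_sheet(config.samples_path)
    if markers is None:
        markers = (
            read_marker_sets(config.markers_path)
            if config.markers_path
            else list(DEFAULT_MARKER_SETS)
        )
    sheet.validate_against(matrix)
    sheet.require_replicates(2)
    log.info(
        "stage=load n_genes=%d n_samples=%d thresholds=%s de=%s pseudocount=%g",
        matrix.n_genes,
        matrix.n_samples,
        config.filter_thresholds,
        config.de_thresholds,
        config.pseudocount,
    )

    manifest = RunManifest(config=config.to_dict(), n_genes_input=matrix.n_genes)

    # --- gene universes -------------------------------------------------
    transcriptome, translatome = define_gene_universes(matrix, sheet, config.filter_thresholds)
    manifest.n_transcriptome = len(transcriptome)
    manifest.n_translatome = len(translatome)
    write_gene_list(transcriptome, out / "transcriptome_genes.txt")
    write_gene_list(translatome, out / "translatome_genes.txt")
    log.info(
        "stage=filter transcriptome=%d translatome=%d", len(transcriptome), len(translatome)
    )

    # --- normalization (per fraction, over the transcriptome universe) --
    for fraction in ("IN", "IP"):
        frac_samples = sheet.samples_for(fraction=fraction)
        norm = quantile_normalize(matrix.subset_samples(frac_samples), transcriptome)
        write_expression_matrix(norm, out / f"normalized_{fraction}.tsv")

    # --- differential occupancy ----------------------------------------
    results = run_de_analysis(
        matrix,
        sheet,
        thresholds=config.de_thresholds,
        fraction="IP",
        pseudocount=config.pseudocount,
        filter_thresholds=config.filter_thresholds,
    )
    calls = [r.call for r in results]
    manifest.n_increased = calls.count("increased")
    manifest.n_decreased = calls.count("decreased")
    manifest.n_unchanged = calls.count("unchanged")
    write_de_table(results, out / "de_table.tsv")
    frame = de_results_frame(results)
    frame[["log2fc", "ssmd", "call"]].to_csv(
        out / "dual_flashlight.tsv", sep="\t", float_format="%.6g"
    )
    log.info(
        "stage=de increased=%d decreased=%d unchanged=%d",
        manifest.n_increased,
        manifest.n_decreased,
        manifest.n_unchanged,
    )
    if config.analyze_in_fraction:
        results_in = run_de_analysis(
            matrix,
            sheet,
            thresholds=config.de_thresholds,
            fraction="IN",
            pseudocount=config.pseudocount,
            filter_thresholds=config.filter_thresholds,
        )
        write_de_table(results_in, out / "de_table_IN.tsv")

    # --- QC --------------------------------------------------------------
    report = QCReport()
    replicate_correlation(matrix, transcriptome, log_transform=True, sheet=sheet, report=report)
    try:
        marker_enrichment(
            matrix, sheet, markers, pseudocount=config.pseudocount, report=report
        )
    except ValidationError as exc:
        log.warning("stage=qc marker enrichment skipped: %s", exc)
    passed, reasons = qc_gate(
        report,
        min_replicate_r=config.min_replicate_r,
        require_marker_sign=config.require_marker_sign and bool(report.set_enrichment),
    )
    manifest.qc_passed = passed
    manifest.qc_reasons = reasons
    manifest.min_within_group_r = report.min_within_group_r
    manifest.marker_set_enrichment = report.set_enrichment
    write_qc_report(report, out / "qc_correlations.tsv", out / "qc_markers.tsv")
    log.info("stage=qc passed=%s reasons=%s", passed, reasons)

    manifest.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime())
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("stage=done elapsed=%.2fs", time.monotonic() - t0)
    return manifest


def _setup_logging(logfile: Path) -> None:
    log.setLevel(logging.INFO)
    have_file = any(
        isinstance(h, logging.FileHandler)
        and getattr(h, "baseFilename", None) == str(logfile.resolve())
        for h in log.handlers
    )
    if not have_file:
        fh = logging.FileHandler(logfile)
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(fh)
    if not any(isinstance(h, logging.StreamHandler) and not isinstance(h, logging.FileHandler) for h in log.handlers):
        sh = logging.StreamHandler()
        sh.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        log.addHandler(sh)
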
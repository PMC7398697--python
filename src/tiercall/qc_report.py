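"""Replicate QC and end-to-end pipeline orchestration.

QC follows the protocol used for the original libraries: pairwise Pearson
correlation of raw first-base coverage values over positions with at
least 10 reads summed across all samples, after removing positions whose
count exceeds the per-library 99.99th percentile (sequencing artefacts
dominate those).  ``run_pipeline`` chains the whole analysis —
coverage -> matrix -> QC -> filter -> test -> call -> classify -> motif ->
context — and writes all artifacts plus a machine-readable summary.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coverage_io import (
    SampleDesign,
    build_count_matrix,
    read_count_table,
    read_design,
    read_genome,
    read_annotation,
    select_samples,
)
from .diffcall import CleavageSiteSet, call_cleavage_sites, run_differential
from .errors import InputError, QCError
from .genomic_context import (
    class_distribution,
    classify_sites,
    gene_site_stats,
    match_srna_5p,
    metagene_profile,
)
from .motif_structure import (
    au_content_profile,
    extract_site_windows,
    mfe_profile,
    position_frequency_matrix,
    write_logo_table,
    write_motif_json,
)
from .synthetic_data import SimConfig, simulate, write_dataset

logger = logging.getLogger("tiercall")


@dataclass
class CorrelationReport:
    """Pairwise Pearson r between libraries after the QC filters."""

    r: pd.DataFrame
    n_positions: int
    min_total: int
    outlier_percentile: float

    @property
    def r_squared(self) -> pd.DataFrame:
        return self.r**2

    def replicate_r2_range(
        self, design: Sequence[SampleDesign]
    ) -> tuple[float, float]:
        """(min, max) r^2 over within-condition replicate pairs."""
        vals = []
        conditions = {(d.strain, d.temperature) for d in design}
        for cond in conditions:
            ids = select_samples(design, *cond)
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    vals.append(float(self.r_squared.loc[ids[i], ids[j]]))
        if not vals:
            raise QCError("no replicate pairs in design")
        return min(vals), max(vals)


def pairwise_pearson(
    matrix: pd.DataFrame,
    min_total: int = 10,
    outlier_percentile: float = 99.99,
) -> CorrelationReport:
    """Pearson correlation of raw counts between all sample pairs.

    Positions with fewer than ``min_total`` reads summed over all samples
    are ignored; positions exceeding the per-library
    ``outlier_percentile`` quantile (linear interpolation) in any library
    are removed.
    """
    if matrix.shape[1] < 2:
        raise QCError("need at least two samples for correlation QC")
    counts = matrix.to_numpy(dtype=np.float64)
    keep = counts.sum(axis=1) >= min_total
    sub = counts[keep]
    if len(sub):
        cutoffs = np.percentile(sub, outlier_percentile, axis=0)
        keep2 = (sub <= cutoffs).all(axis=1)
        sub = sub[keep2]
    if len(sub) < 2:
        raise QCError(
            f"only {len(sub)} positions survive the QC filters; need >= 2"
        )
    r = pd.DataFrame(np.corrcoef(sub, rowvar=False), index=matrix.columns, columns=matrix.columns)
    return CorrelationReport(
        r=r,
        n_positions=int(len(sub)),
        min_total=min_total,
        outlier_percentile=outlier_percentile,
    )


# ---------------------------------------------------------------------------
# Pipeline configuration and orchestration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    In synthetic mode the generator settings come from ``sim``; in file
    mode ``genome``, ``annotation``, ``design`` and ``counts_dir`` point at
    existing inputs (count TSVs named <sample_id>.tsv).
    """

    outdir: str = "tiercall_run"
    mode: str = "synthetic"  # "synthetic" or "counts"
    genome: str | None = None
    annotation: str | None = None
    design: str | None = None
    counts_dir: str | None = None
    min_coverage: int = 20
    min_fold_change: float = 3.0
    max_padj: float = 0.05
    direction: str = "depleted"
    require_null_at_30: bool = False
    qc_min_total: int = 10
    qc_outlier_percentile: float = 99.99
    metagene_window: int = 100
    mfe_max_sites: int = 60
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)

    def validate(self) -> None:
        if self.mode not in ("synthetic", "counts"):
            raise InputError(f"mode must be synthetic or counts, got {self.mode!r}")
        if min(self.min_coverage, self.min_fold_change, self.max_padj) <= 0:
            raise InputError("thresholds must be positive")
        if self.mode == "counts":
            for name in ("genome", "annotation", "design", "counts_dir"):
                path = getattr(self, name)
                if path is None or not Path(path).exists():
                    raise InputError(f"mode=counts requires existing {name} path")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        return cls(**raw, sim=sim)

    def to_yaml(self, path: str | Path) -> None:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            return obj

        with open(path, "w") as fh:
            yaml.safe_dump(plain(asdict(self)), fh, sort_keys=True)


def _round_floats(obj, ndigits=6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def write_sites_bed(sites: CleavageSiteSet, path: str | Path) -> None:
    """Called sites as BED6; score = min(1000, round(-10 log10 padj))."""
    with open(path, "w") as fh:
        for i, ((chrom, pos, strand), row) in enumerate(sites.table.iterrows(), 1):
            padj = max(float(row["padj"]), 1e-300)
            score = int(min(1000, round(-10.0 * np.log10(padj))))
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\tsite{i:06d}\t{score}\t{strand}\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full TIER-seq analysis and write all artifacts.

    Returns the run summary (also written to ``summary.json``): number of
    sites called, class counts/fractions, per-gene density summary,
    consensus motif, matched sRNA count, replicate QC range and — in
    synthetic mode — recovery against the planted truth.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run_pipeline_inner(config, outdir)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _stage(name: str):
    logger.info("stage: %s", name)


def _run_pipeline_inner(config: RunConfig, outdir: Path) -> dict:
    logger.info(
        "tiercall %s | python %s | seed %d | thresholds: min_coverage=%d "
        "min_fold_change=%.3g max_padj=%.3g direction=%s qc_min_total=%d "
        "qc_outlier_percentile=%.4g",
        __version__,
        platform.python_version(),
        config.seed,
        config.min_coverage,
        config.min_fold_change,
        config.max_padj,
        config.direction,
        config.qc_min_total,
        config.qc_outlier_percentile,
    )

    truth = None
    if config.mode == "synthetic":
        _stage("simulate")
        sim_cfg = SimConfig(**{**asdict(config.sim), "seed": config.seed})
        dataset = simulate(sim_cfg)
        write_dataset(dataset, outdir / "inputs")
        genome = dataset.truth.genome
        annotation = dataset.truth.annotation
        design = dataset.truth.design
        coverages = dataset.coverages
        truth = dataset.truth
    else:
        _stage("load")
        genome = read_genome(config.genome)
        annotation = read_annotation(config.annotation, genome)
        design = read_design(config.design)
        coverages = {
            d.sample_id: read_count_table(
                Path(config.counts_dir) / f"{d.sample_id}.tsv", genome, d.sample_id
            )
            for d in design
        }

    _stage("count matrix")
    matrix = build_count_matrix(coverages, design)
    logger.info("matrix: %d positions x %d samples", *matrix.shape)

    _stage("replicate QC")
    qc = pairwise_pearson(
        matrix,
        min_total=config.qc_min_total,
        outlier_percentile=config.qc_outlier_percentile,
    )
    qc.r.to_csv(outdir / "qc_pearson_r.tsv", sep="\t")
    qc.r_squared.to_csv(outdir / "qc_pearson_r2.tsv", sep="\t")
    rep_r2 = qc.replicate_r2_range(design)

    _stage("differential test")
    results, sf = run_differential(
        matrix, design, min_coverage=config.min_coverage
    )
    sf.to_csv(outdir / "size_factors.tsv", sep="\t")
    results.to_csv(outdir / "position_tests.tsv", sep="\t", float_format="%.6g")

    _stage("site calling")
    sites = call_cleavage_sites(
        results,
        min_fold_change=config.min_fold_change,
        max_padj=config.max_padj,
        direction=config.direction,
        require_null_at_30=config.require_null_at_30,
    )
    logger.info("called %d cleavage sites", len(sites))

    _stage("classification")
    classified = classify_sites(sites.table, annotation)
    dist = class_distribution(classified) if len(classified) else None
    stats = gene_site_stats(classified, annotation)
    meta_start = metagene_profile(
        classified, annotation, "start_codon", window=config.metagene_window
    )
    meta_stop = metagene_profile(
        classified, annotation, "stop_codon", window=config.metagene_window
    )
    srna_matches = match_srna_5p(classified, annotation)

    _stage("motif")
    windows = extract_site_windows(classified, genome) if len(classified) else []
    motif_payload = None
    if windows:
        model = position_frequency_matrix(windows)
        if len(windows) == len(classified):
            classified["motif_window"] = windows
        motif_payload = write_motif_json(model, outdir / "motif.json")
        write_logo_table(model, outdir / "motif_logo.tsv")

    _stage("context profiles")
    if len(classified):
        au = au_content_profile(classified, genome)
        au.to_frame().to_csv(
            outdir / "au_profile.tsv", sep="\t", index=False, float_format="%.6g"
        )
        mfe = mfe_profile(classified, genome, max_sites=config.mfe_max_sites)
        mfe.to_frame().to_csv(
            outdir / "mfe_profile.tsv", sep="\t", index=False, float_format="%.6g"
        )

    _stage("write site tables")
    classified.to_csv(outdir / "sites.tsv", sep="\t", float_format="%.6g")
    write_sites_bed(CleavageSiteSet(classified, sites.thresholds), outdir / "sites.bed")
    if dist is not None:
        dist.to_frame().to_csv(outdir / "class_distribution.tsv", sep="\t", float_format="%.6g")
    stats.per_gene.to_csv(outdir / "gene_site_stats.tsv", sep="\t", float_format="%.6g")
    meta_start.to_frame().to_csv(
        outdir / "metagene_start.tsv", sep="\t", index=False, float_format="%.6g"
    )
    meta_stop.to_frame().to_csv(
        outdir / "metagene_stop.tsv", sep="\t", index=False, float_format="%.6g"
    )
    srna_matches.to_csv(outdir / "srna_matches.tsv", sep="\t", index=False)

    summary: dict = {
        "tiercall_version": __version__,
        "seed": config.seed,
        "mode": config.mode,
        "thresholds": {
            "min_coverage": config.min_coverage,
            "min_fold_change": config.min_fold_change,
            "max_padj": config.max_padj,
            "direction": config.direction,
        },
        "n_positions_in_matrix": int(matrix.shape[0]),
        "n_positions_tested": int(len(results)),
        "n_sites_called": int(len(sites)),
        "class_counts": {} if dist is None else {k: int(v) for k, v in dist.counts.items()},
        "class_fractions": {}
        if dist is None
        else {k: float(v) for k, v in dist.fractions.items()},
        "median_sites_per_kb": stats.median_sites_per_kb,
        "mean_sites_per_kb": stats.mean_sites_per_kb,
        "consensus": None if motif_payload is None else motif_payload["consensus_rna_display"],
        "matched_srna_count": int(len(srna_matches)),
        "qc": {
            "n_positions": qc.n_positions,
            "replicate_r2_min": rep_r2[0],
            "replicate_r2_max": rep_r2[1],
        },
    }
    if truth is not None:
        truth_keys = truth.site_keys()
        called_keys = set(sites.table.index)
        tp = len(truth_keys & called_keys)
        summary["recovery"] = {
            "n_planted": len(truth_keys),
            "n_called": len(called_keys),
            "n_true_positive": tp,
            "recall": tp / len(truth_keys) if truth_keys else 0.0,
            "precision": tp / len(called_keys) if called_keys else 0.0,
        }
    summary = _round_floats(summary)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("summary written to %s", outdir / "summary.json")
    return summary
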
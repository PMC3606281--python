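"""File formats, configuration, and the staged pipeline driver.

All tabular interchange is plain TSV/CSV; anomaly calls use a BED-like
dialect with 1-based, inclusive coordinates (stated in a header comment
line). A run manifest (JSON) records seeds and parameters so any output
can be regenerated byte-for-byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association_analysis as assoc
from .anomaly_filtering import FilterConfig, filter_anomalies, review_queue, screen_low_quality_sample
from .baf_segmentation import (
    ChangePointConfig,
    build_tbaf_series,
    call_candidate_anomalies,
    cbs_segment,
)
from .genome_model import GenomeModel, SnpManifest, build_default_genome, generate_manifest
from .mosaic_classification import cluster_anomalies, compute_metrics, finalize_calls
from .sample_qc import QcThresholds, compute_baf_sd, screen_samples
from .synthetic_cohort import CohortConfig, IntensityProfile, simulate_cohort

__all__ = [
    "PipelineConfig",
    "read_intensity",
    "write_intensity",
    "read_phenotypes",
    "write_phenotypes",
    "write_calls",
    "read_calls",
    "run_pipeline",
]

logger = logging.getLogger("mosaicscan")

INTENSITY_COLUMNS = ["snp_id", "chromosome", "position", "genotype", "baf", "lrr"]
PHENOTYPE_COLUMNS = [
    "subject_id", "age_baseline", "cohort", "followup_time",
    "event", "diagnosis", "diagnosis_time", "prior_history",
]
CALL_HEADER = "# mosaicscan calls; coordinates are 1-based, inclusive at both ends\n"


class ParseError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Paths plus every stage's tunables; the global seed feeds all stages."""

    output_dir: str = "mosaicscan_out"
    manifest_path: str | None = None
    genome_path: str | None = None
    intensity_dir: str | None = None
    phenotype_path: str | None = None
    simulate: bool = True
    cohort: CohortConfig = field(default_factory=CohortConfig)
    qc: QcThresholds = field(default_factory=QcThresholds)
    changepoint: ChangePointConfig = field(default_factory=ChangePointConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    lrr_cnloh_threshold: float = 0.05
    snps_per_mb: float = 60.0
    n_chromosomes: int = 6
    chromosome_length_range: tuple = (60_000_000, 120_000_000)
    seed: int = 0


def write_intensity(profile: IntensityProfile, path) -> None:
    profile.data[INTENSITY_COLUMNS].to_csv(path, sep="\t", index=False)


def read_intensity(path, subject_id: str | None = None) -> IntensityProfile:
    """Read a per-subject intensity TSV with validation.

    Raises ``ParseError`` naming the first offending line for missing
    columns, unsorted positions, or BAF outside [0, 1].
    """
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    missing = set(INTENSITY_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    bad = df.index[(df["baf"] < 0) | (df["baf"] > 1)]
    if len(bad):
        raise ParseError(f"{path}: BAF outside [0, 1] at line {bad[0] + 2}")
    for chrom, grp in df.groupby("chromosome", sort=False):
        pos = grp["position"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            at = grp.index[np.argmax(np.diff(pos) <= 0) + 1]
            raise ParseError(f"{path}: positions not strictly increasing at line {at + 2}")
    if subject_id is None:
        subject_id = Path(path).stem
    return IntensityProfile(subject_id=subject_id, data=df)


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    phenotypes[PHENOTYPE_COLUMNS].to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(PHENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    bad = df.index[df["followup_time"] < 0]
    if len(bad):
        raise ParseError(f"{path}: negative follow-up at line {bad[0] + 2}")
    return df


def write_calls(calls: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(CALL_HEADER)
        calls.to_csv(fh, sep="\t", index=False)


def read_calls(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def _detect_subject(profile: IntensityProfile, genome: GenomeModel, config: PipelineConfig):
    """Segmentation + candidate calling + filtering for one profile."""
    series_by_chrom = {}
    segments_by_chrom = {}
    candidates = []
    for chrom in profile.chromosome_names:
        series = build_tbaf_series(profile, chrom)
        if len(series) == 0:
            continue
        series_by_chrom[chrom] = series
        segments = cbs_segment(series, config.changepoint)
        segments_by_chrom[chrom] = segments
        candidates.extend(
            call_candidate_anomalies(segments, series, config.changepoint, profile.subject_id)
        )
    filtered = filter_anomalies(candidates, series_by_chrom, genome, config.filters)
    return series_by_chrom, segments_by_chrom, candidates, filtered


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute simulate -> sample QC -> detect -> filter -> classify ->
    associate -> report, writing artifacts under ``output_dir``.

    Without phenotypes the association stage is skipped (detection-only
    mode). Returns a dict of in-memory results; artifacts and a run
    manifest land in ``output_dir``.
    """
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- inputs ---------------------------------------------------------
    if config.genome_path:
        genome = GenomeModel.from_yaml(config.genome_path)
    else:
        genome = build_default_genome(
            n_chromosomes=config.n_chromosomes,
            length_range=config.chromosome_length_range,
            seed=config.seed,
        )
    if config.manifest_path:
        manifest = SnpManifest.from_tsv(config.manifest_path)
    else:
        manifest = generate_manifest(genome, config.snps_per_mb, seed=config.seed + 1)

    truth = None
    phenotypes = None
    if config.simulate:
        cohort_cfg = config.cohort.with_(seed=config.seed)
        profiles, truth, phenotypes = simulate_cohort(cohort_cfg, genome, manifest)
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        write_phenotypes(phenotypes, out / "phenotypes.csv")
    else:
        if not config.intensity_dir:
            raise ValueError("intensity_dir required when simulate=False")
        profiles = [read_intensity(p) for p in sorted(Path(config.intensity_dir).glob("*.tsv"))]
        if config.phenotype_path:
            phenotypes = read_phenotypes(config.phenotype_path)
    genome.to_yaml(out / "genome.yaml")
    manifest.to_tsv(out / "manifest.tsv")
    logger.info("inputs ready: %d subjects (%.1fs)", len(profiles), time.time() - t0)

    # --- sample QC ------------------------------------------------------
    qc_table = screen_samples(profiles, config.qc)
    qc_table.to_csv(out / "sample_qc.tsv", sep="\t", index=False)
    eligible_ids = set(qc_table.loc[qc_table["eligible"], "subject_id"])
    profiles = [p for p in profiles if p.subject_id in eligible_ids]
    logger.info("sample QC: %d eligible (%.1fs)", len(profiles), time.time() - t0)

    # --- detection + filtering + low-quality screen ---------------------
    all_filtered = []
    metrics_list = []
    anomalies_by_subject_chrom: dict = {}
    profile_by_id = {p.subject_id: p for p in profiles}
    lowq_rows = []
    for profile in profiles:
        series_by_chrom, segments_by_chrom, candidates, filtered = _detect_subject(
            profile, genome, config
        )
        excluded = [
            (a.segment.chromosome, a.segment.start_pos, a.segment.end_pos) for a in filtered
        ]
        try:
            baf_sd = compute_baf_sd(profile, excluded)
        except ValueError:
            baf_sd = np.nan
        lrr_vals = profile.data["lrr"]
        # spurious-segmentation screen discounts *called* candidates, pre-filter
        n_anom_by_chrom: dict[str, int] = {}
        for a in candidates:
            n_anom_by_chrom[a.segment.chromosome] = n_anom_by_chrom.get(a.segment.chromosome, 0) + 1
        status, reasons = screen_low_quality_sample(
            baf_sd if np.isfinite(baf_sd) else 0.0,
            float(lrr_vals.std(ddof=1)),
            {c: len(s) for c, s in segments_by_chrom.items()},
            {c: len(s) for c, s in series_by_chrom.items()},
            config.filters,
            n_anomalous_by_chrom=n_anom_by_chrom,
        )
        lowq_rows.append(
            {"subject_id": profile.subject_id, "status": status, "reasons": ";".join(reasons)}
        )
        if status != "eligible":
            continue
        for a in filtered:
            anomalies_by_subject_chrom.setdefault(
                (a.subject_id, a.segment.chromosome), []
            ).append(a)
        all_filtered.extend(filtered)
    pd.DataFrame(lowq_rows).to_csv(out / "low_quality_screen.tsv", sep="\t", index=False)
    logger.info("detection: %d filtered anomalies (%.1fs)", len(all_filtered), time.time() - t0)

    # --- classification -------------------------------------------------
    for a in all_filtered:
        metrics_list.append(
            compute_metrics(
                a,
                profile_by_id[a.subject_id],
                anomalies_by_subject_chrom[(a.subject_id, a.segment.chromosome)],
            )
        )
    model = cluster_anomalies(metrics_list, seed=config.seed)
    calls = finalize_calls(
        all_filtered, metrics_list, model, manifest, genome,
        lrr_threshold=config.lrr_cnloh_threshold, config=config.filters,
    )
    write_calls(calls, out / "calls.tsv")
    review_queue(all_filtered, config.filters).to_csv(out / "review_queue.tsv", sep="\t", index=False)
    logger.info("classification: %d calls (%.1fs)", len(calls), time.time() - t0)

    # --- association + reports -----------------------------------------
    results = {
        "genome": genome,
        "manifest": manifest,
        "qc": qc_table,
        "calls": calls,
        "truth": truth,
    }
    if phenotypes is not None:
        records, exclusion_log = assoc.apply_incidence_filters(phenotypes)
        records = assoc.attach_exposure(records, calls)
        exclusion_log.to_csv(out / "incidence_exclusions.tsv", sep="\t", index=False)
        tables = assoc.build_report_tables(calls, records)
        tables["location_event"].to_csv(out / "table_location_event.tsv", sep="\t")
        tables["per_diagnosis"].to_csv(out / "table_per_diagnosis.tsv", sep="\t", index=False)
        tables["hazard_ratios"].to_csv(out / "table_hazard_ratios.tsv", sep="\t", index=False)
        results["records"] = records
        results["tables"] = tables
        for label, curve in assoc.km_curve(records, "exposure_any_mosaic").items():
            curve.to_csv(out / f"km_any_mosaic_{label}.csv", index=False)
    else:
        logger.info("no phenotypes: association stage skipped")

    run_manifest = {
        "seed": config.seed,
        "n_subjects": len(profiles),
        "n_calls": int(len(calls)),
        "parameters": {
            "cohort": asdict(config.cohort),
            "qc": asdict(config.qc),
            "changepoint": asdict(config.changepoint),
            "filters": asdict(config.filters),
            "lrr_cnloh_threshold": config.lrr_cnloh_threshold,
        },
        "elapsed_s": round(time.time() - t0, 2),
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(run_manifest, fh, indent=2, default=str)
    logger.info("pipeline complete (%.1fs)", time.time() - t0)
    return results


def load_pipeline_config(path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file of nested stage sections."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = dict(raw)
    for key, cls in (
        ("cohort", CohortConfig),
        ("qc", QcThresholds),
        ("changepoint", ChangePointConfig),
        ("filters", FilterConfig),
    ):
        if key in kwargs and isinstance(kwargs[key], dict):
            kwargs[key] = cls(**kwargs[key])
    return PipelineConfig(**kwargs)
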
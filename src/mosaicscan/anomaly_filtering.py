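"""Post-detection quality control for candidate anomalies.

Stage order is fixed: sample-level low-quality screen, then per-chromosome
merging of adjacent candidates, then centromere-span resolution, then the
minimum-probe filter. Rerunning the anomaly-level stages on their own
output is a no-op.

The segment-ratio screens count *excess* segments (change-points) rather
than raw segment counts: a clean chromosome always yields one segment, so
oversegmentation is measured as (segments - 1) per chromosome and as the
total number of accepted change-points genome-wide, each relative to the
eligible-SNP count at the matching scope.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .baf_segmentation import CandidateAnomaly, Segment, TBafSeries
from .genome_model import GenomeModel

__all__ = [
    "FilterConfig",
    "screen_low_quality_sample",
    "merge_adjacent",
    "resolve_centromere_span",
    "min_probe_filter",
    "filter_anomalies",
    "review_queue",
]


@dataclass(frozen=True)
class FilterConfig:
    sd_thresh: float = 0.1
    sng_seg_thresh: float = 0.0008
    auto_seg_thresh: float = 0.0001
    merge_max_gap_probes: int = 300
    merge_lrr_tol: float = 0.05
    centromere_min_probes_per_side: int = 500
    min_baf_probes: int = 50
    large_anomaly_bp: int = 2_000_000

    def __post_init__(self) -> None:
        for name in (
            "sd_thresh", "sng_seg_thresh", "auto_seg_thresh", "merge_max_gap_probes",
            "merge_lrr_tol", "centromere_min_probes_per_side", "min_baf_probes",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def screen_low_quality_sample(
    baf_sd: float,
    lrr_sd: float,
    n_segments_by_chrom: dict[str, int],
    eligible_by_chrom: dict[str, int],
    config: FilterConfig = FilterConfig(),
    n_anomalous_by_chrom: dict[str, int] | None = None,
) -> tuple[str, list[str]]:
    """Classify a sample as eligible or low_quality after segmentation.

    ``baf_sd`` / ``lrr_sd`` are non-anomalous standard deviations; a sample
    is low quality when either exceeds ``sd_thresh``, when any single
    chromosome is oversegmented beyond ``sng_seg_thresh``, or when the
    genome-wide segmentation ratio exceeds ``auto_seg_thresh``.

    Oversegmentation is measured as spurious change-points per eligible
    SNP: a clean chromosome contributes one segment, and each called
    anomaly legitimately accounts for up to two change-points, so the
    excess on a chromosome is ``max(0, n_segments - 1 - 2 x n_anomalies)``
    (``n_anomalous_by_chrom`` gives the per-chromosome called-anomaly
    counts; omit it to screen raw segmentation). Returns (status, reasons).
    """
    reasons = []
    if baf_sd > config.sd_thresh:
        reasons.append("high_baf_sd")
    if lrr_sd > config.sd_thresh:
        reasons.append("high_lrr_sd")
    n_anomalous_by_chrom = n_anomalous_by_chrom or {}
    total_excess = 0
    total_elig = 0
    for chrom, n_segs in n_segments_by_chrom.items():
        n_elig = eligible_by_chrom.get(chrom, 0)
        if n_elig == 0:
            continue
        excess = max(n_segs - 1 - 2 * n_anomalous_by_chrom.get(chrom, 0), 0)
        total_excess += excess
        total_elig += n_elig
        if excess / n_elig > config.sng_seg_thresh:
            if "oversegmented_chromosome" not in reasons:
                reasons.append("oversegmented_chromosome")
    if total_elig and total_excess / total_elig > config.auto_seg_thresh:
        reasons.append("oversegmented_genome")
    return ("low_quality" if reasons else "eligible"), reasons


def _remake(anom: CandidateAnomaly, series: TBafSeries, lo: int, hi: int) -> CandidateAnomaly:
    """Rebuild a candidate over eligible indices [lo, hi), recomputing metrics."""
    seg = Segment(
        chromosome=series.chromosome,
        start_index=lo,
        end_index=hi - 1,
        start_pos=int(series.position[lo]),
        end_pos=int(series.position[hi - 1]),
        n_probes=hi - lo,
        mean_tbaf=float(np.mean(series.tbaf[lo:hi])),
        mean_lrr=float(np.mean(series.lrr[lo:hi])),
    )
    z = (seg.mean_tbaf - anom.baseline_tbaf) * np.sqrt(seg.n_probes) / anom.baseline_sigma
    return replace(anom, segment=seg, z_score=float(z))


def merge_adjacent(
    anomalies: list[CandidateAnomaly],
    series: TBafSeries,
    config: FilterConfig = FilterConfig(),
) -> list[CandidateAnomaly]:
    """Merge runs of nearby candidates with similar LRR on one chromosome.

    Two consecutive candidates are unioned when fewer than
    ``merge_max_gap_probes`` eligible probes separate them and their mean
    LRR values differ by less than ``merge_lrr_tol``; the merge is applied
    left-to-right until a fixpoint, and merged metrics are recomputed over
    the union including the gap probes.
    """
    if not anomalies:
        return []
    anomalies = sorted(anomalies, key=lambda a: a.segment.start_index)
    for prev, nxt in zip(anomalies[:-1], anomalies[1:]):
        if nxt.segment.start_index <= prev.segment.end_index:
            raise ValueError("anomalies must be non-overlapping")
    out = [anomalies[0]]
    for nxt in anomalies[1:]:
        prev = out[-1]
        gap = nxt.segment.start_index - prev.segment.end_index - 1
        if gap < config.merge_max_gap_probes and abs(
            nxt.segment.mean_lrr - prev.segment.mean_lrr
        ) < config.merge_lrr_tol:
            out[-1] = _remake(prev, series, prev.segment.start_index, nxt.segment.end_index + 1)
        else:
            out.append(nxt)
    return out


def resolve_centromere_span(
    anomaly: CandidateAnomaly,
    series: TBafSeries,
    genome: GenomeModel,
    config: FilterConfig = FilterConfig(),
) -> list[CandidateAnomaly]:
    """Keep a centromere-spanning anomaly intact only with enough support
    on both sides; otherwise split it at the centromere.

    A spanning anomaly needs at least ``centromere_min_probes_per_side``
    eligible probes on each arm; failing that, it is split into per-arm
    anomalies with recomputed metrics (each still subject to the
    minimum-probe filter downstream). Anomalies within one arm pass
    through unchanged.
    """
    chrom = genome[anomaly.segment.chromosome]
    seg = anomaly.segment
    if not (seg.start_pos < chrom.centromere_start and seg.end_pos > chrom.centromere_end):
        return [anomaly]
    lo, hi = seg.start_index, seg.end_index + 1
    pos = series.position[lo:hi]
    n_p = int(np.sum(pos < chrom.centromere_start))
    n_q = int(np.sum(pos > chrom.centromere_end))
    if n_p >= config.centromere_min_probes_per_side and n_q >= config.centromere_min_probes_per_side:
        return [anomaly]
    parts = []
    if n_p > 0:
        parts.append(_remake(anomaly, series, lo, lo + n_p))
    if n_q > 0:
        parts.append(_remake(anomaly, series, hi - n_q, hi))
    return parts


def min_probe_filter(anomaly: CandidateAnomaly, config: FilterConfig = FilterConfig()) -> bool:
    """True when the anomaly has at least ``min_baf_probes`` eligible probes."""
    return anomaly.segment.n_probes >= config.min_baf_probes


def filter_anomalies(
    anomalies: list[CandidateAnomaly],
    series_by_chrom: dict[str, TBafSeries],
    genome: GenomeModel,
    config: FilterConfig = FilterConfig(),
) -> list[CandidateAnomaly]:
    """Merge, resolve centromeres, and apply the minimum-probe filter."""
    out: list[CandidateAnomaly] = []
    by_chrom: dict[str, list[CandidateAnomaly]] = {}
    for a in anomalies:
        by_chrom.setdefault(a.segment.chromosome, []).append(a)
    for chrom, group in by_chrom.items():
        series = series_by_chrom[chrom]
        merged = merge_adjacent(group, series, config)
        resolved: list[CandidateAnomaly] = []
        for a in merged:
            resolved.extend(resolve_centromere_span(a, series, genome, config))
        out.extend(a for a in resolved if min_probe_filter(a, config))
    return sorted(out, key=lambda a: (a.segment.chromosome, a.segment.start_pos))


def review_queue(anomalies: list[CandidateAnomaly], config: FilterConfig = FilterConfig()) -> pd.DataFrame:
    """Anomalies larger than the review size (default 2 Mb), exported for
    optional human inspection in place of the original manual review."""
    rows = [
        {
            "subject_id": a.subject_id,
            "chromosome": a.segment.chromosome,
            "start_pos": a.segment.start_pos,
            "end_pos": a.segment.end_pos,
            "length_bp": a.segment.length_bp,
            "n_probes": a.segment.n_probes,
            "mean_lrr": a.segment.mean_lrr,
            "z_score": a.z_score,
        }
        for a in anomalies
        if a.segment.length_bp > config.large_anomaly_bp
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id", "chromosome", "start_pos", "end_pos",
            "length_bp", "n_probes", "mean_lrr", "z_score",
        ],
    )
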
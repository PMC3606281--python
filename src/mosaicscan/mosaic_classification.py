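"""Mosaic vs constitutive separation and copy-number-state assignment.

Each filtered anomaly is summarized by two metrics measured against its
chromosome's non-anomalous background:

* LRR deviation — median(anomalous LRR) - median(non-anomalous LRR);
* BAF MAD — median |anomalous BAF - median(non-anomalous BAF)| over
  eligible (het/missing) SNPs.

In this plane, constitutive (germline, full-clonal) duplications collect
in a tight cloud around the trisomic signature (LRR deviation log2(3/2),
BAF MAD 1/6), while mosaic anomalies spread according to their clonal
fraction. k-means (k = 3) on the standardized metrics locates that cloud;
anomalies within two MAD radii of its median are labelled constitutive and
the rest mosaic. Mosaic anomalies then get a copy-number state from the
sign of the LRR deviation against a +/-0.05 threshold, a chromosomal
location type, a >2 Mb flag, and a clonal-fraction estimate inverting the
BAF band arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .anomaly_filtering import FilterConfig
from .baf_segmentation import CandidateAnomaly, select_eligible_snps
from .genome_model import GenomeModel, SnpManifest, classify_location
from .synthetic_cohort import IntensityProfile, expected_lrr_shift

__all__ = [
    "AnomalyMetrics",
    "ClusterModel",
    "compute_metrics",
    "cluster_anomalies",
    "flag_constitutive",
    "classify_event",
    "estimate_mosaic_fraction",
    "finalize_calls",
]

#: Theoretical (lrr_dev, baf_mad) signature of a full-clonal trisomy:
#: LRR shift log2(3/2) and het bands at 1/3, 2/3.
TRISOMY_SIGNATURE = (expected_lrr_shift("gain", 1.0), 1.0 / 6.0)


@dataclass(frozen=True)
class AnomalyMetrics:
    lrr_dev: float
    baf_mad: float
    n_probes: int
    length_bp: int
    genome_wide_background: bool = False  # True when no same-chromosome background existed

    def __post_init__(self) -> None:
        if self.baf_mad < 0:
            raise ValueError("baf_mad must be non-negative")
        if self.length_bp <= 0:
            raise ValueError("length_bp must be positive")


@dataclass
class ClusterModel:
    centroids: np.ndarray          # (3, 2) in original metric units
    labels: np.ndarray             # cluster index per anomaly
    constitutive_cluster: int | None
    cluster_medians: np.ndarray    # (3, 2) componentwise medians, standardized space
    mad_radii: np.ndarray          # per-cluster median distance to the median
    scale_mean: np.ndarray
    scale_sd: np.ndarray

    def standardize(self, xy: np.ndarray) -> np.ndarray:
        return (np.asarray(xy, dtype=float) - self.scale_mean) / self.scale_sd


def compute_metrics(
    anomaly: CandidateAnomaly,
    profile: IntensityProfile,
    chromosome_anomalies: list[CandidateAnomaly] | None = None,
) -> AnomalyMetrics:
    """Per-anomaly (LRR deviation, BAF MAD) against the chromosome background.

    The non-anomalous background is the same chromosome outside *all*
    anomalies on it (pass them via ``chromosome_anomalies``); when the
    anomalies cover the whole chromosome the background falls back to the
    genome-wide non-anomalous probes and the result is flagged. LRR medians
    use all probes; BAF MAD uses eligible (het/missing) probes only, since
    homozygote BAF carries no imbalance signal.
    """
    chrom = anomaly.segment.chromosome
    others = chromosome_anomalies if chromosome_anomalies is not None else [anomaly]
    sub = profile.chromosome(chrom)
    pos = sub["position"].to_numpy()
    inside_this = (pos >= anomaly.segment.start_pos) & (pos <= anomaly.segment.end_pos)
    inside_any = np.zeros(len(sub), dtype=bool)
    for a in others:
        inside_any |= (pos >= a.segment.start_pos) & (pos <= a.segment.end_pos)

    if not inside_this.any():
        raise ValueError("anomaly covers no probes on its chromosome")

    eligible_local = np.zeros(len(sub), dtype=bool)
    eligible_local[select_eligible_snps(profile, chrom)] = True

    fallback = False
    background = sub.loc[~inside_any]
    if background.empty or not (eligible_local & ~inside_any).any():
        fallback = True
        all_data = profile.data
        out_mask = np.ones(len(all_data), dtype=bool)
        this_chrom = (all_data["chromosome"] == chrom).to_numpy()
        out_mask[this_chrom] = ~inside_any
        background = all_data.loc[out_mask]
        bg_baf_pool = background.loc[
            (background["genotype"] == "AB") | (background["genotype"] == "missing"), "baf"
        ]
    else:
        bg_baf_pool = sub.loc[eligible_local & ~inside_any, "baf"]

    lrr_dev = float(
        np.median(sub.loc[inside_this, "lrr"]) - np.median(background["lrr"])
    )
    med_bg_baf = float(np.median(bg_baf_pool))
    anom_baf = sub.loc[inside_this & eligible_local, "baf"].to_numpy()
    if anom_baf.size == 0:
        raise ValueError("anomaly contains no eligible probes")
    baf_mad = float(np.median(np.abs(anom_baf - med_bg_baf)))
    return AnomalyMetrics(
        lrr_dev=lrr_dev,
        baf_mad=baf_mad,
        n_probes=anomaly.segment.n_probes,
        length_bp=anomaly.segment.length_bp,
        genome_wide_background=fallback,
    )


def cluster_anomalies(metrics: list[AnomalyMetrics], seed: int = 0) -> ClusterModel:
    """Fit seeded k-means (k = 3, 20 restarts) on standardized metrics.

    The constitutive cluster is the one whose centroid lies nearest the
    theoretical trisomic signature (measured in standardized units). With
    fewer than 3 anomalies no model can be fitted: every anomaly is treated
    as putatively mosaic (``constitutive_cluster`` is None).
    """
    xy = np.array([(m.lrr_dev, m.baf_mad) for m in metrics], dtype=float)
    if len(xy) < 3:
        return ClusterModel(
            centroids=np.zeros((0, 2)),
            labels=np.zeros(len(xy), dtype=int),
            constitutive_cluster=None,
            cluster_medians=np.zeros((0, 2)),
            mad_radii=np.zeros(0),
            scale_mean=np.zeros(2),
            scale_sd=np.ones(2),
        )
    mean = xy.mean(axis=0)
    sd = xy.std(axis=0)
    sd[sd == 0] = 1.0
    z = (xy - mean) / sd
    km = KMeans(n_clusters=3, n_init=20, random_state=seed)
    labels = km.fit_predict(z)

    sig_z = (np.array(TRISOMY_SIGNATURE) - mean) / sd
    dists = np.linalg.norm(km.cluster_centers_ - sig_z, axis=1)
    counts = np.bincount(labels, minlength=3)
    dists[counts == 0] = np.inf  # duplicate points can leave clusters empty
    const_cluster = int(np.argmin(dists))

    medians = np.empty((3, 2))
    radii = np.empty(3)
    for k in range(3):
        members = z[labels == k]
        if len(members) == 0:
            medians[k] = km.cluster_centers_[k]
            radii[k] = 0.0
        else:
            medians[k] = np.median(members, axis=0)
            radii[k] = float(np.median(np.linalg.norm(members - medians[k], axis=1)))
    return ClusterModel(
        centroids=km.cluster_centers_ * sd + mean,
        labels=labels,
        constitutive_cluster=const_cluster,
        cluster_medians=medians,
        mad_radii=radii,
        scale_mean=mean,
        scale_sd=sd,
    )


def flag_constitutive(
    metrics: AnomalyMetrics, model: ClusterModel, radius_floor: float = 1e-6
) -> str:
    """Label one anomaly constitutive or mosaic under the two-MAD rule.

    The anomaly is constitutive when its distance to the constitutive
    cluster's median is within two MAD radii; the raw median distance is
    scaled by 1.4826 so the MAD acts as a robust standard deviation (as in
    candidate calling), keeping ~95% of a Gaussian cluster inside.
    """
    if model.constitutive_cluster is None:
        return "mosaic"
    k = model.constitutive_cluster
    z = model.standardize([(metrics.lrr_dev, metrics.baf_mad)])[0]
    d = float(np.linalg.norm(z - model.cluster_medians[k]))
    return "constitutive" if d <= 2 * max(1.4826 * model.mad_radii[k], radius_floor) else "mosaic"


def classify_event(metrics: AnomalyMetrics, lrr_threshold: float = 0.05) -> str:
    """Copy-number state from the LRR deviation: gain above +threshold,
    loss below -threshold, copy-neutral LOH inside the band (inclusive)."""
    if metrics.lrr_dev > lrr_threshold:
        return "gain"
    if metrics.lrr_dev < -lrr_threshold:
        return "loss"
    return "cnloh"


def estimate_mosaic_fraction(event_type: str, baf_mad: float) -> float:
    """Invert the heterozygote band split to a clonal-fraction estimate.

    With band offset D = baf_mad: CN-LOH gives f = 2D, loss f = 4D/(1+2D),
    gain f = 4D/(1-2D); results are clipped to [0, 1].
    """
    d = float(baf_mad)
    if not 0.0 <= d <= 0.5:
        raise ValueError("baf_mad must be in [0, 0.5]")
    if event_type == "cnloh":
        f = 2 * d
    elif event_type == "loss":
        f = 4 * d / (1 + 2 * d)
    elif event_type == "gain":
        if d >= 0.5:
            raise ValueError("gain band offset must be < 0.5")
        f = 4 * d / (1 - 2 * d)
    else:
        raise ValueError(f"unknown event_type {event_type!r}")
    return float(np.clip(f, 0.0, 1.0))


def finalize_calls(
    anomalies: list[CandidateAnomaly],
    metrics: list[AnomalyMetrics],
    model: ClusterModel,
    manifest: SnpManifest,
    genome: GenomeModel,
    lrr_threshold: float = 0.05,
    config: FilterConfig = FilterConfig(),
) -> pd.DataFrame:
    """Assemble the final call table.

    One row per anomaly: mosaic/constitutive class, copy-number state and
    clonal-fraction estimate (mosaic only), location type, and the strict
    >2 Mb large-event flag. Coordinates are 1-based inclusive.
    """
    rows = []
    for anom, m in zip(anomalies, metrics):
        cls = flag_constitutive(m, model)
        if cls == "mosaic":
            etype = classify_event(m, lrr_threshold)
            try:
                f_hat = estimate_mosaic_fraction(etype, min(m.baf_mad, 0.499))
            except ValueError:
                f_hat = np.nan
        else:
            etype = ""
            f_hat = np.nan
        rows.append(
            {
                "chromosome": anom.segment.chromosome,
                "start": anom.segment.start_pos,
                "end": anom.segment.end_pos,
                "subject_id": anom.subject_id,
                "class": cls,
                "event_type": etype,
                "location": classify_location(
                    anom.segment.chromosome, anom.segment.start_pos, anom.segment.end_pos,
                    manifest, genome,
                ),
                "n_probes": anom.segment.n_probes,
                "lrr_dev": m.lrr_dev,
                "baf_mad": m.baf_mad,
                "f_hat": f_hat,
                "is_large": anom.segment.length_bp > config.large_anomaly_bp,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chromosome", "start", "end", "subject_id", "class", "event_type",
            "location", "n_probes", "lrr_dev", "baf_mad", "f_hat", "is_large",
        ],
    )
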
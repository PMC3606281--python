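"""BAF-driven anomaly detection: eligible SNPs, the tBAF transform, circular
binary segmentation, and candidate calling against a per-chromosome baseline.

Detection works on the subset of SNPs that are heterozygous or missing
under the genotype caller — exactly the loci whose BAF moves when a cell
subpopulation carries an allelic imbalance (hets split into bands; hets
shifted far enough stop being called at all). Their BAF is folded into

    tBAF = sqrt(min(BAF, 1 - BAF, |BAF - median BAF|))

which is near zero for both well-behaved hets (BAF ~ median ~ 0.5) and for
homozygote-like dropouts (BAF ~ 0 or 1), and elevated inside anomalies.
Change-points in tBAF are found by circular binary segmentation with a
seeded permutation test; segments whose mean tBAF sits significantly above
the chromosome's non-anomalous baseline become candidate anomalies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._cbs_kernels import max_arc_stat, perm_exceedances
from .synthetic_cohort import IntensityProfile

__all__ = [
    "ChangePointConfig",
    "TBafSeries",
    "Segment",
    "CandidateAnomaly",
    "select_eligible_snps",
    "transform_baf",
    "build_tbaf_series",
    "cbs_segment",
    "call_candidate_anomalies",
    "detect_anomalies",
    "candidates_to_frame",
]

TBAF_MAX = float(np.sqrt(0.5))


@dataclass(frozen=True)
class ChangePointConfig:
    """Tuning of the change-point search and candidate calling.

    ``calling_z`` applies to the baseline-relative elevation of a segment's
    mean tBAF expressed in robust standard errors (MAD-based SD of baseline
    tBAF scaled by sqrt(n_probes)); the default 4 keeps the false-call rate
    on clean chromosomes near zero while leaving ample margin for real
    events. ``min_length_bp`` enforces the 50 kb detection floor.
    """

    alpha: float = 0.01
    n_permutations: int = 1000
    min_seg_width: int = 5
    calling_z: float = 4.0
    min_length_bp: int = 50_000
    mad_floor: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if self.min_seg_width < 1:
            raise ValueError("min_seg_width must be >= 1")


@dataclass
class TBafSeries:
    """Eligible-SNP view of one chromosome of one profile."""

    chromosome: str
    index: np.ndarray  # positional indices into the chromosome's SNP order
    position: np.ndarray
    baf: np.ndarray
    tbaf: np.ndarray
    lrr: np.ndarray
    median_baf: float

    def __len__(self) -> int:
        return len(self.index)


@dataclass(frozen=True)
class Segment:
    chromosome: str
    start_index: int  # eligible-SNP indices, inclusive
    end_index: int
    start_pos: int
    end_pos: int
    n_probes: int
    mean_tbaf: float
    mean_lrr: float

    @property
    def length_bp(self) -> int:
        return self.end_pos - self.start_pos + 1


@dataclass(frozen=True)
class CandidateAnomaly:
    subject_id: str
    segment: Segment
    z_score: float
    baseline_tbaf: float
    baseline_sigma: float = 1.0


def select_eligible_snps(profile: IntensityProfile, chromosome: str) -> np.ndarray:
    """Positional indices (within the chromosome's SNP order) of the
    heterozygous and missing calls."""
    sub = profile.chromosome(chromosome)
    geno = sub["genotype"].to_numpy()
    return np.flatnonzero((geno == "AB") | (geno == "missing"))


def transform_baf(baf, median_baf: float) -> np.ndarray:
    """Elementwise sqrt(min(BAF, 1 - BAF, |BAF - median_baf|))."""
    baf = np.asarray(baf, dtype=float)
    if baf.size and (np.min(baf) < 0.0 or np.max(baf) > 1.0):
        raise ValueError("BAF values must lie in [0, 1]")
    return np.sqrt(np.minimum(np.minimum(baf, 1.0 - baf), np.abs(baf - median_baf)))


def build_tbaf_series(profile: IntensityProfile, chromosome: str) -> TBafSeries:
    """Assemble the eligible-SNP tBAF series for one chromosome.

    The median BAF in the transform is taken over the chromosome's eligible
    SNPs, so a whole-chromosome anomaly shifts the reference as little as
    possible at chromosome scope.
    """
    sub = profile.chromosome(chromosome)
    idx = select_eligible_snps(profile, chromosome)
    baf = sub["baf"].to_numpy()[idx]
    lrr = sub["lrr"].to_numpy()[idx]
    pos = sub["position"].to_numpy()[idx]
    median_baf = float(np.median(baf)) if len(baf) else 0.5
    return TBafSeries(
        chromosome=chromosome,
        index=idx,
        position=pos,
        baf=baf,
        tbaf=transform_baf(baf, median_baf),
        lrr=lrr,
        median_baf=median_baf,
    )


def _make_segment(series: TBafSeries, lo: int, hi: int) -> Segment:
    """Segment over eligible indices [lo, hi) of the series."""
    return Segment(
        chromosome=series.chromosome,
        start_index=lo,
        end_index=hi - 1,
        start_pos=int(series.position[lo]),
        end_pos=int(series.position[hi - 1]),
        n_probes=hi - lo,
        mean_tbaf=float(np.mean(series.tbaf[lo:hi])),
        mean_lrr=float(np.mean(series.lrr[lo:hi])),
    )


def cbs_segment(series: TBafSeries, config: ChangePointConfig = ChangePointConfig()) -> list[Segment]:
    """Partition the eligible SNPs of a chromosome into mean-homogeneous
    segments by recursive circular binary segmentation.

    At each step the arc maximizing the standardized arc-vs-complement mean
    difference is found exhaustively (both sides at least
    ``min_seg_width``); the split is accepted when its seeded permutation
    p-value is below ``alpha``, and the search recurses into the resulting
    pieces. The output always covers the series contiguously.
    """
    x = np.asarray(series.tbaf, dtype=float)
    n = len(x)
    if n == 0:
        return []
    max_exceed = int(np.floor(config.alpha * config.n_permutations))
    counter = [0]

    def next_seed() -> int:
        counter[0] += 1
        return (config.seed * 1_000_003 + counter[0]) % (2**31 - 1)

    bounds: list[tuple[int, int]] = []

    def split(lo: int, hi: int) -> None:
        m = hi - lo
        if m < 2 * config.min_seg_width:
            bounds.append((lo, hi))
            return
        seg = x[lo:hi]
        if np.std(seg) == 0.0:
            bounds.append((lo, hi))
            return
        observed, i, j = max_arc_stat(seg, config.min_seg_width)
        if i == 0 and j == m:
            bounds.append((lo, hi))
            return
        _, exceed = perm_exceedances(
            seg, observed, config.min_seg_width, config.n_permutations, max_exceed, next_seed()
        )
        if exceed > max_exceed or exceed / config.n_permutations >= config.alpha:
            bounds.append((lo, hi))
            return
        cuts = [lo, lo + i, lo + j, hi]
        for a, b in zip(cuts[:-1], cuts[1:]):
            if b > a:
                split(a, b)

    split(0, n)
    bounds.sort()
    return [_make_segment(series, lo, hi) for lo, hi in bounds]


def call_candidate_anomalies(
    segments: list[Segment],
    series: TBafSeries,
    config: ChangePointConfig = ChangePointConfig(),
    subject_id: str = "",
) -> list[CandidateAnomaly]:
    """Flag segments whose mean tBAF is elevated above the chromosome baseline.

    The baseline is the median tBAF over SNPs in segments not yet flagged;
    flagging iterates (flag, recompute) until stable so that large anomalies
    do not drag the baseline upward. A segment becomes a candidate when its
    one-sided robust z-score reaches ``calling_z`` and it spans at least
    ``min_length_bp``.
    """
    if not segments:
        return []
    spans = {id(s): (s.start_index, s.end_index + 1) for s in segments}
    flagged: set[int] = set()
    while True:
        base_vals = np.concatenate(
            [series.tbaf[spans[id(s)][0]: spans[id(s)][1]] for s in segments if id(s) not in flagged]
        ) if any(id(s) not in flagged for s in segments) else np.array([])
        if base_vals.size == 0:
            break
        baseline = float(np.median(base_vals))
        mad = float(np.median(np.abs(base_vals - baseline)))
        sigma = max(1.4826 * mad, config.mad_floor)
        new_flags = {
            id(s)
            for s in segments
            if id(s) not in flagged
            and (s.mean_tbaf - baseline) * np.sqrt(s.n_probes) / sigma >= config.calling_z
        }
        if not new_flags:
            break
        flagged |= new_flags

    base_vals = np.concatenate(
        [series.tbaf[spans[id(s)][0]: spans[id(s)][1]] for s in segments if id(s) not in flagged]
    ) if any(id(s) not in flagged for s in segments) else series.tbaf
    baseline = float(np.median(base_vals))
    mad = float(np.median(np.abs(base_vals - baseline)))
    sigma = max(1.4826 * mad, config.mad_floor)

    out = []
    for s in segments:
        if id(s) not in flagged:
            continue
        if s.length_bp < config.min_length_bp:
            continue
        z = (s.mean_tbaf - baseline) * np.sqrt(s.n_probes) / sigma
        out.append(
            CandidateAnomaly(
                subject_id=subject_id, segment=s, z_score=float(z),
                baseline_tbaf=baseline, baseline_sigma=sigma,
            )
        )
    return out


def detect_anomalies(
    profile: IntensityProfile, config: ChangePointConfig = ChangePointConfig()
) -> list[CandidateAnomaly]:
    """Run segmentation + candidate calling over every chromosome of a profile."""
    out: list[CandidateAnomaly] = []
    for chrom in profile.chromosome_names:
        series = build_tbaf_series(profile, chrom)
        if len(series) == 0:
            continue
        segments = cbs_segment(series, config)
        out.extend(call_candidate_anomalies(segments, series, config, profile.subject_id))
    return out


def candidates_to_frame(candidates: list[CandidateAnomaly]) -> pd.DataFrame:
    cols = [
        "subject_id", "chromosome", "start_pos", "end_pos",
        "n_probes", "mean_tbaf", "mean_lrr", "z_score",
    ]
    rows = [
        (
            c.subject_id, c.segment.chromosome, c.segment.start_pos, c.segment.end_pos,
            c.segment.n_probes, c.segment.mean_tbaf, c.segment.mean_lrr, c.z_score,
        )
        for c in candidates
    ]
    return pd.DataFrame(rows, columns=cols)
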
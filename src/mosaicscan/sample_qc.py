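"""Sample-level quality screens: call rate, BAF noise, duplicate detection.

Exclusion boundaries are strict, as conventionally stated: a sample fails
the call-rate screen when its rate is strictly below the threshold (default
98%), and the BAF-SD screen when its non-anomalous autosomal BAF standard
deviation strictly exceeds the threshold (default 0.06).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_cohort import IntensityProfile

__all__ = [
    "QcThresholds",
    "compute_call_rate",
    "compute_baf_sd",
    "ibs_proportion",
    "screen_samples",
]

_GENO_CODE = {"AA": 0, "AB": 1, "BB": 2}


@dataclass(frozen=True)
class QcThresholds:
    min_call_rate: float = 0.98
    max_baf_sd: float = 0.06
    ibs_duplicate_threshold: float = 0.95

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "max_baf_sd", "ibs_duplicate_threshold"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def compute_call_rate(profile: IntensityProfile) -> float:
    """Fraction of SNPs with a non-missing genotype call."""
    geno = profile.data["genotype"]
    if len(geno) == 0:
        raise ValueError("profile has no SNPs")
    return float((geno != "missing").mean())


def _outside_mask(data: pd.DataFrame, excluded_intervals) -> np.ndarray:
    mask = np.ones(len(data), dtype=bool)
    if excluded_intervals:
        chrom = data["chromosome"].to_numpy()
        pos = data["position"].to_numpy()
        for c, s, e in excluded_intervals:
            mask &= ~((chrom == c) & (pos >= s) & (pos <= e))
    return mask


def compute_baf_sd(
    profile: IntensityProfile,
    excluded_intervals=None,
    per_chromosome_median: bool = False,
) -> float:
    """BAF standard deviation at het-called SNPs outside known anomalies.

    ``excluded_intervals`` is an iterable of (chromosome, start, end) tuples
    masking detected anomalies, making the estimate "non-anomalous". Before
    anomalies are known, ``per_chromosome_median=True`` gives a robust first
    pass: the median of per-chromosome het-BAF SDs, insensitive to a single
    aberrant chromosome.
    """
    data = profile.data
    mask = _outside_mask(data, excluded_intervals) & (data["genotype"].to_numpy() == "AB")
    sub = data.loc[mask]
    if len(sub) < 2:
        raise ValueError("need at least 2 het SNPs outside excluded intervals")
    if per_chromosome_median:
        sds = sub.groupby("chromosome", sort=False)["baf"].std(ddof=1).dropna()
        if sds.empty:
            raise ValueError("no chromosome with >= 2 het SNPs")
        return float(sds.median())
    return float(sub["baf"].std(ddof=1))


def ibs_proportion(genotypes_a, genotypes_b) -> float:
    """Mean identity-by-state / 2 over jointly non-missing SNPs.

    Genotypes are coded by B-allele dosage (AA=0, AB=1, BB=2); per-SNP IBS
    is ``2 - |dose_a - dose_b|``.
    """
    a = pd.Series(genotypes_a).map(_GENO_CODE)
    b = pd.Series(genotypes_b).map(_GENO_CODE)
    if len(a) != len(b):
        raise ValueError("genotype vectors must be aligned")
    ok = a.notna().to_numpy() & b.notna().to_numpy()
    if not ok.any():
        raise ValueError("no SNP where both genotypes are non-missing")
    diff = np.abs(a.to_numpy(dtype=float)[ok] - b.to_numpy(dtype=float)[ok])
    return float(np.mean(2.0 - diff) / 2.0)


def screen_samples(
    profiles: list[IntensityProfile],
    thresholds: QcThresholds = QcThresholds(),
    excluded_intervals: dict | None = None,
    ibs_max_snps: int = 2000,
    ibs_seed: int = 0,
) -> pd.DataFrame:
    """Apply all sample screens; returns an eligibility table.

    Columns: subject_id, call_rate, baf_sd, eligible, reasons (semicolon
    separated from {low_call_rate, high_baf_sd, duplicate}).
    ``excluded_intervals`` maps subject_id -> list of (chrom, start, end) for
    anomaly-aware BAF-SD computation; without it the robust per-chromosome
    median first pass is used. Of a duplicate pair, the member with the
    lower call rate is flagged (ties broken by subject_id, keeping the
    lexicographically smaller). IBS is computed on a deterministic subsample
    of at most ``ibs_max_snps`` SNPs for tractability.
    """
    excluded_intervals = excluded_intervals or {}
    rows = []
    doses = []
    for prof in profiles:
        cr = compute_call_rate(prof)
        try:
            sd = compute_baf_sd(
                prof,
                excluded_intervals.get(prof.subject_id),
                per_chromosome_median=prof.subject_id not in excluded_intervals,
            )
        except ValueError:
            sd = np.nan
        rows.append({"subject_id": prof.subject_id, "call_rate": cr, "baf_sd": sd})
        doses.append(prof.data["genotype"].map(_GENO_CODE).to_numpy(dtype=float))
    table = pd.DataFrame(rows)

    reasons: dict[str, set] = {r["subject_id"]: set() for r in rows}
    for r in rows:
        if r["call_rate"] < thresholds.min_call_rate:
            reasons[r["subject_id"]].add("low_call_rate")
        if np.isfinite(r["baf_sd"]) and r["baf_sd"] > thresholds.max_baf_sd:
            reasons[r["subject_id"]].add("high_baf_sd")

    # pairwise IBS duplicate screen on a fixed SNP subsample
    if len(profiles) > 1:
        n_snps = len(doses[0])
        rng = np.random.default_rng(ibs_seed)
        idx = (
            np.sort(rng.choice(n_snps, size=ibs_max_snps, replace=False))
            if n_snps > ibs_max_snps
            else np.arange(n_snps)
        )
        mat = np.vstack([d[idx] for d in doses])
        for i in range(len(profiles)):
            for j in range(i + 1, len(profiles)):
                ok = np.isfinite(mat[i]) & np.isfinite(mat[j])
                if not ok.any():
                    continue
                ibs = float(np.mean(2.0 - np.abs(mat[i][ok] - mat[j][ok])) / 2.0)
                if ibs >= thresholds.ibs_duplicate_threshold:
                    a, b = rows[i], rows[j]
                    if a["call_rate"] != b["call_rate"]:
                        loser = min(a, b, key=lambda r: r["call_rate"])["subject_id"]
                    else:
                        loser = max(a["subject_id"], b["subject_id"])
                    reasons[loser].add("duplicate")

    table["reasons"] = [";".join(sorted(reasons[s])) for s in table["subject_id"]]
    table["eligible"] = table["reasons"] == ""
    return table[["subject_id", "call_rate", "baf_sd", "eligible", "reasons"]]
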
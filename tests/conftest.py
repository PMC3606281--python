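"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mosaicscan.genome_model import ChromosomeSpec, GenomeModel, generate_manifest
from mosaicscan.synthetic_cohort import CohortConfig


# --------------------------------------------------------------------------
# independent oracles
# --------------------------------------------------------------------------

def mixture_bands_oracle(event_type: str, f: float, genotype: str = "AB"):
    """Brute-force per-cell allele-copy mixture: enumerate the aberrant-cell
    copy configurations and average B copies / total copies over the
    two-population mixture. Independent of the closed forms under test."""
    base = {"AA": (0, 0), "AB": (1, 0), "BB": (1, 1)}[genotype]  # B per homolog
    b_normal, t_normal = sum(base), 2
    bands = set()
    for affected in (0, 1):  # which homolog the event hits
        kept = base[1 - affected]
        hit = base[affected]
        if event_type == "loss":
            b_ab, t_ab = kept, 1
        elif event_type == "gain":
            b_ab, t_ab = kept + 2 * hit, 3
        elif event_type == "cnloh":
            b_ab, t_ab = 2 * kept, 2
        else:
            raise ValueError(event_type)
        num = f * b_ab + (1 - f) * b_normal
        den = f * t_ab + (1 - f) * t_normal
        bands.add(round(num / den, 12))
    return sorted(bands)


def mixture_lrr_oracle(event_type: str, f: float) -> float:
    total = {"loss": 1, "gain": 3, "cnloh": 2}[event_type]
    mean_copies = f * total + (1 - f) * 2
    return float(np.log2(mean_copies / 2))


def max_arc_stat_oracle(x: np.ndarray, min_width: int):
    """Exhaustive numpy scan for the maximal circular-arc statistic."""
    n = len(x)
    s = np.concatenate([[0.0], np.cumsum(x)])
    tot = s[-1]
    best, arg = -1.0, None
    for k in range(min_width, n - min_width + 1):
        d = np.abs(s[k:] - s[:-k] - k * tot / n) / np.sqrt(k * (n - k) / n)
        i = int(np.argmax(d))
        if d[i] > best:
            best, arg = float(d[i]), (i, i + k)
    return best, arg


def cox_grid_oracle(time, event, x, lo=-5.0, hi=5.0, n_grid=200_001) -> float:
    """Brute-force grid maximization of the Cox partial likelihood for a
    single covariate (no tied event times)."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    x = np.asarray(x, float)
    betas = np.linspace(lo, hi, n_grid)
    ll = np.zeros_like(betas)
    order = np.argsort(time)
    time, event, x = time[order], event[order], x[order]
    for i in np.flatnonzero(event == 1):
        risk = time >= time[i]
        ll += betas * x[i] - np.log(np.exp(betas[:, None] * x[risk][None, :]).sum(axis=1))
    return float(betas[np.argmax(ll)])


def fisher_enumeration_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided exact test by direct enumeration with exact binomials."""
    from math import comb

    n, r1, c1 = a + b + c + d, a + b, a + c
    denom = comb(n, c1)
    probs = {
        x: comb(r1, x) * comb(n - r1, c1 - x) / denom
        for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1)
    }
    p_obs = probs[a]
    return min(sum(p for p in probs.values() if p <= p_obs * (1 + 1e-7)), 1.0)


# --------------------------------------------------------------------------
# fixtures
# --------------------------------------------------------------------------

@pytest.fixture(scope="session")
def genome() -> GenomeModel:
    return GenomeModel(
        (
            ChromosomeSpec("chrA", 60_000_000, 27_000_000, 28_200_000, "metacentric"),
            ChromosomeSpec("chrB", 40_000_000, 2_000_000, 2_800_000, "acrocentric"),
        )
    )


@pytest.fixture(scope="session")
def manifest(genome):
    return generate_manifest(genome, snps_per_mb=60.0, seed=11)


@pytest.fixture()
def cohort_config() -> CohortConfig:
    return CohortConfig(seed=7)


def make_profile(rows: list[tuple]) -> "pd.DataFrame":
    """Build an intensity frame from (snp_id, chrom, pos, genotype, baf, lrr)."""
    return pd.DataFrame(
        rows, columns=["snp_id", "chromosome", "position", "genotype", "baf", "lrr"]
    )
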
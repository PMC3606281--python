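"""Synthetic autosome models, SNP manifests, and interval-location typing.

Coordinates are 1-based and inclusive at both ends throughout the package,
matching conventional SNP-array manifest files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ChromosomeSpec",
    "GenomeModel",
    "SnpManifest",
    "build_default_genome",
    "generate_manifest",
    "classify_location",
]


@dataclass(frozen=True)
class ChromosomeSpec:
    """An autosome with an explicit centromere interval.

    ``arm_type`` distinguishes metacentric chromosomes (centromere near the
    middle) from acrocentric ones, whose p arm is negligible: for those the
    centromere must start within the first 10% of the chromosome.
    """

    name: str
    length: int
    centromere_start: int
    centromere_end: int
    arm_type: str = "metacentric"

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.name}: chromosome length must be positive")
        if not (0 < self.centromere_start < self.centromere_end < self.length):
            raise ValueError(
                f"{self.name}: centromere [{self.centromere_start}, "
                f"{self.centromere_end}] must lie strictly inside (0, {self.length})"
            )
        if self.arm_type not in ("metacentric", "acrocentric"):
            raise ValueError(f"{self.name}: unknown arm_type {self.arm_type!r}")
        if self.arm_type == "acrocentric" and self.centromere_start / self.length >= 0.1:
            raise ValueError(
                f"{self.name}: acrocentric centromere must start within the "
                "first 10% of the chromosome"
            )


@dataclass(frozen=True)
class GenomeModel:
    """An ordered collection of autosomes (sex chromosomes are out of scope)."""

    chromosomes: tuple[ChromosomeSpec, ...]

    def __post_init__(self) -> None:
        if len(self.chromosomes) == 0:
            raise ValueError("genome must contain at least one chromosome")
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")

    def __getitem__(self, name: str) -> ChromosomeSpec:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(f"unknown chromosome {name!r}")

    def __contains__(self, name: str) -> bool:
        return any(c.name == name for c in self.chromosomes)

    def to_yaml(self, path) -> None:
        payload = {
            "chromosomes": [
                {
                    "name": c.name,
                    "length": int(c.length),
                    "centromere_start": int(c.centromere_start),
                    "centromere_end": int(c.centromere_end),
                    "arm_type": c.arm_type,
                }
                for c in self.chromosomes
            ]
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GenomeModel":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(tuple(ChromosomeSpec(**c) for c in payload["chromosomes"]))


@dataclass
class SnpManifest:
    """Ordered SNP positions per chromosome.

    ``data`` has columns (snp_id, chromosome, position); positions are
    strictly increasing within each chromosome and never fall inside a
    centromere interval.
    """

    data: pd.DataFrame
    _by_chrom: dict = field(default_factory=dict, repr=False, compare=False)

    REQUIRED_COLUMNS = ("snp_id", "chromosome", "position")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        for chrom, grp in self.data.groupby("chromosome", sort=False):
            pos = grp["position"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"{chrom}: manifest positions must be strictly increasing")
            self._by_chrom[chrom] = grp.reset_index(drop=True)

    def chromosome(self, name: str) -> pd.DataFrame:
        try:
            return self._by_chrom[name]
        except KeyError:
            raise KeyError(f"chromosome {name!r} not in manifest") from None

    def positions(self, name: str) -> np.ndarray:
        return self.chromosome(name)["position"].to_numpy()

    def n_snps(self, name: str) -> int:
        return len(self.chromosome(name))

    @property
    def chromosome_names(self) -> list[str]:
        return list(self._by_chrom)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SnpManifest":
        return cls(pd.read_csv(path, sep="\t", dtype={"chromosome": str}))


def build_default_genome(
    n_chromosomes: int = 22,
    length_range: tuple[int, int] = (50_000_000, 250_000_000),
    acrocentric_fraction: float = 0.2,
    seed: int = 0,
) -> GenomeModel:
    """Draw a deterministic synthetic autosome set.

    Lengths are sampled uniformly from ``length_range`` and sorted in
    decreasing order (mimicking karyotype numbering). A fixed fraction of
    chromosomes, taken from the short end, is made acrocentric with the
    centromere at 5% of the length; the rest are metacentric with the
    centromere centred at 40-55% of the length. Centromeres span 2% of the
    chromosome.
    """
    if n_chromosomes < 1:
        raise ValueError("n_chromosomes must be >= 1")
    lo, hi = length_range
    if lo <= 0 or hi <= 0 or lo > hi:
        raise ValueError("length_range must be a positive, ordered pair")
    if not 0.0 <= acrocentric_fraction <= 1.0:
        raise ValueError("acrocentric_fraction must be in [0, 1]")

    rng = np.random.default_rng(seed)
    lengths = np.sort(rng.integers(lo, hi + 1, size=n_chromosomes))[::-1]
    n_acro = int(round(acrocentric_fraction * n_chromosomes))
    chroms = []
    for i, length in enumerate(lengths):
        length = int(length)
        name = f"chr{i + 1}"
        cen_width = max(int(0.02 * length), 2)
        if i >= n_chromosomes - n_acro:
            cen_start = max(int(0.05 * length), 1)
            arm_type = "acrocentric"
        else:
            centre = rng.uniform(0.40, 0.55)
            cen_start = int(centre * length - cen_width / 2)
            arm_type = "metacentric"
        chroms.append(
            ChromosomeSpec(
                name=name,
                length=length,
                centromere_start=cen_start,
                centromere_end=cen_start + cen_width,
                arm_type=arm_type,
            )
        )
    return GenomeModel(tuple(chroms))


def generate_manifest(
    genome: GenomeModel, snps_per_mb: float = 200.0, seed: int = 0
) -> SnpManifest:
    """Scatter SNPs uniformly over the non-centromeric genome.

    The SNP count per chromosome is Poisson with mean
    ``snps_per_mb x non-centromeric length``; positions are uniform outside
    the centromere, sorted, and deduplicated.
    """
    if snps_per_mb <= 0:
        raise ValueError("snps_per_mb must be positive")
    rng = np.random.default_rng(seed)
    frames = []
    for chrom in genome.chromosomes:
        cen_len = chrom.centromere_end - chrom.centromere_start
        open_len = chrom.length - cen_len
        n = rng.poisson(snps_per_mb * open_len / 1e6)
        if n == 0:
            continue
        # Draw in the gapless coordinate system, then shift past the centromere.
        raw = np.sort(rng.integers(1, open_len + 1, size=n))
        pos = np.where(raw >= chrom.centromere_start, raw + cen_len, raw)
        pos = np.unique(pos)
        frames.append(
            pd.DataFrame(
                {
                    "snp_id": [f"{chrom.name}_snp{j + 1:06d}" for j in range(len(pos))],
                    "chromosome": chrom.name,
                    "position": pos,
                }
            )
        )
    if not frames:
        data = pd.DataFrame(columns=list(SnpManifest.REQUIRED_COLUMNS))
    else:
        data = pd.concat(frames, ignore_index=True)
    return SnpManifest(data)


def classify_location(
    chromosome: str,
    start: int,
    end: int,
    manifest: SnpManifest,
    genome: GenomeModel,
    end_tolerance_probes: int = 3,
) -> str:
    """Type an interval as whole / p_terminal / q_terminal / interstitial.

    An interval "reaches" a chromosome end if it covers a SNP within
    ``end_tolerance_probes`` probes of the terminal manifest SNP; reaching
    both ends makes it whole, one end terminal, neither interstitial. The
    rule is purely positional, with no cytogenetic interpretation, so on
    acrocentric chromosomes an interval covering the last SNP but not the
    first is still q_terminal.
    """
    if chromosome not in genome:
        raise KeyError(f"unknown chromosome {chromosome!r}")
    pos = manifest.positions(chromosome)
    if len(pos) == 0:
        raise ValueError(f"{chromosome}: manifest has no SNPs")
    k = min(end_tolerance_probes, len(pos) - 1)
    reaches_p = start <= pos[k]
    reaches_q = end >= pos[-1 - k]
    if reaches_p and reaches_q:
        return "whole"
    if reaches_p:
        return "p_terminal"
    if reaches_q:
        return "q_terminal"
    return "interstitial"
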
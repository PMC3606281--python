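"""Synthetic cohorts of SNP-array intensity profiles with clonal mosaic events.

The generator plants three kinds of acquired anomaly — mosaic gains, losses
and copy-neutral LOH (CN-LOH) at a clonal fraction ``f`` — alongside
constitutive (full-clonal, germline-like) CNVs, and emits per-SNP B-allele
frequency (BAF) and log R ratio (LRR) signals with Gaussian noise plus a
genotype-caller model. Survival phenotypes with an elevated hazard for
mosaic carriers are generated for the association stage.

The signal model assumes one of the two mixing cell populations is diploid:
a fraction ``f`` of cells carries the anomaly, ``1 - f`` are normal. BAF at
a heterozygous SNP is then B copies / total copies averaged over cells, and
LRR is idealized as log2(mean copy number / 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome_model import GenomeModel, SnpManifest

__all__ = [
    "MosaicEventSpec",
    "ConstitutiveCnvSpec",
    "SubjectSpec",
    "IntensityProfile",
    "CohortConfig",
    "expected_baf_bands",
    "expected_lrr_shift",
    "simulate_subject",
    "simulate_cohort",
    "simulate_survival",
]

EVENT_TYPES = ("gain", "loss", "cnloh")
GENOTYPES = ("AA", "AB", "BB", "missing")

#: Diagnosis mix among incident hematologic cancers (leukemia, non-Hodgkin
#: lymphoma, Hodgkin lymphoma, multiple myeloma, myelodysplastic syndrome).
DIAGNOSIS_PROBS = {
    "leukemia": 51 / 229,
    "NHL": 120 / 229,
    "HL": 6 / 229,
    "MM": 46 / 229,
    "MDS": 6 / 229,
}


@dataclass(frozen=True)
class MosaicEventSpec:
    chromosome: str
    start: int
    end: int
    event_type: str
    f: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("event start must be < end")
        if not 0.0 < self.f <= 1.0:
            raise ValueError("clonal fraction f must be in (0, 1]")
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event_type {self.event_type!r}")


@dataclass(frozen=True)
class ConstitutiveCnvSpec:
    chromosome: str
    start: int
    end: int
    copy_number: int = 3

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("CNV start must be < end")
        if self.copy_number not in (1, 3):
            raise ValueError("copy_number must be 1 or 3")


@dataclass
class SubjectSpec:
    subject_id: str
    age_baseline: float
    cohort: str
    mosaic_events: list = field(default_factory=list)
    constitutive_cnvs: list = field(default_factory=list)


@dataclass
class IntensityProfile:
    """Per-subject SNP-level data, aligned 1:1 with the manifest.

    ``data`` columns: snp_id, chromosome, position, genotype, baf, lrr.
    ``genotype`` is the observed (caller) call in {AA, AB, BB, missing}.
    """

    subject_id: str
    data: pd.DataFrame

    def chromosome(self, name: str) -> pd.DataFrame:
        sub = self.data[self.data["chromosome"] == name]
        if sub.empty:
            raise KeyError(f"chromosome {name!r} not in profile")
        return sub

    @property
    def chromosome_names(self) -> list[str]:
        return list(self.data["chromosome"].unique())


@dataclass
class CohortConfig:
    """Study conditions for cohort simulation.

    Defaults describe a population resembling the one the method was
    designed for: elderly subjects (ages 50-89), ~1.4% mosaic carriers, a
    mosaic event-type mix of 8% gains / 41.5% losses / 50.5% CN-LOH, and an
    incident hematologic cancer hazard elevated 5.5-fold for carriers.
    """

    n_subjects: int = 200
    het_rate: float = 0.33
    missing_rate: float = 0.005
    baf_noise_sd: float = 0.03
    lrr_noise_sd: float = 0.08
    lrr_compression: float = 1.0

    # anomaly planting
    mosaic_prevalence: float = 0.014
    prevalence_log_or_per_year: float = 0.0
    extra_events_rate: float = 0.18  # events per carrier = 1 + Poisson(rate)
    event_type_probs: dict = field(
        default_factory=lambda: {"gain": 0.08, "loss": 0.415, "cnloh": 0.505}
    )
    f_range: tuple = (0.1, 0.8)
    event_size_range: tuple = (2_000_000, 30_000_000)  # log-uniform, bp
    cnv_prevalence: float = 0.02
    cnv_size_range: tuple = (1_000_000, 5_000_000)  # log-uniform, bp

    # genotype caller
    hom_call_max_baf: float = 0.15  # AA below, BB above 1 - this
    het_call_range: tuple = (0.35, 0.65)

    # survival
    baseline_hazard: float = 0.0017  # events per person-year
    hr_mosaic: float = 5.5
    hr_per_year_age: float = 1.04
    max_followup: float = 12.0
    prior_history_rate: float = 0.02
    age_range: tuple = (50.0, 89.0)
    cohort_labels: tuple = ("studyA", "studyB")
    cohort_probs: tuple = (0.2, 0.8)
    diagnosis_probs: dict = field(default_factory=lambda: dict(DIAGNOSIS_PROBS))

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("het_rate", "missing_rate", "mosaic_prevalence", "cnv_prevalence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("baseline_hazard", "hr_mosaic", "hr_per_year_age"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def with_(self, **kwargs) -> "CohortConfig":
        return replace(self, **kwargs)


def expected_baf_bands(event_type: str, f: float, genotype: str = "AB") -> tuple:
    """Expected BAF band means for a genotype inside an anomaly.

    Averaging allele copies over the cell mixture (fraction ``f`` aberrant,
    ``1 - f`` diploid), a heterozygote splits into two bands symmetric about
    0.5; homozygotes stay pinned at 0 and 1 for every event type (the B
    allele count is 0 or equals the total count in every cell).
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError("clonal fraction f must be in [0, 1]")
    if event_type not in EVENT_TYPES:
        raise ValueError(f"unknown event_type {event_type!r}")
    if genotype == "AA":
        return (0.0,)
    if genotype == "BB":
        return (1.0,)
    if genotype != "AB":
        raise ValueError(f"unknown genotype {genotype!r}")
    if event_type == "loss":
        return ((1 - f) / (2 - f), 1 / (2 - f))
    if event_type == "gain":
        return (1 / (2 + f), (1 + f) / (2 + f))
    return ((1 - f) / 2, (1 + f) / 2)  # cnloh


def expected_lrr_shift(event_type: str, f: float) -> float:
    """Idealized LRR shift log2(c/2), c = mean copy number over the mixture."""
    if not 0.0 <= f <= 1.0:
        raise ValueError("clonal fraction f must be in [0, 1]")
    if event_type == "loss":
        return float(np.log2((2 - f) / 2))
    if event_type == "gain":
        return float(np.log2((2 + f) / 2))
    if event_type == "cnloh":
        return 0.0
    raise ValueError(f"unknown event_type {event_type!r}")


def _event_layers(spec: SubjectSpec):
    """Flatten mosaic events and constitutive CNVs to (chrom, start, end, type, f)."""
    layers = []
    for ev in spec.mosaic_events:
        layers.append((ev.chromosome, ev.start, ev.end, ev.event_type, ev.f))
    for cnv in spec.constitutive_cnvs:
        etype = "gain" if cnv.copy_number == 3 else "loss"
        layers.append((cnv.chromosome, cnv.start, cnv.end, etype, 1.0))
    return layers


def simulate_subject(
    spec: SubjectSpec,
    manifest: SnpManifest,
    config: CohortConfig,
    rng: np.random.Generator,
) -> IntensityProfile:
    """Forward-simulate one subject's BAF/LRR profile over the manifest.

    True genotypes are drawn per SNP (heterozygous with ``het_rate``); inside
    an anomaly a heterozygote falls on either split band with equal
    probability (phase is random per SNP). Observed calls come from the
    caller model on the noisy BAF — which is what makes heterozygotes inside
    strong anomalies go missing — with an additional uniform no-call rate.
    """
    chrom_names = set(manifest.chromosome_names)
    for chrom, *_ in _event_layers(spec):
        if chrom not in chrom_names:
            raise ValueError(f"event chromosome {chrom!r} not in manifest")

    data = manifest.data.copy()
    n = len(data)
    u = rng.random(n)
    true_geno = np.where(u < config.het_rate, "AB", np.where(u < (1 + config.het_rate) / 2, "AA", "BB"))

    baf_mean = np.where(true_geno == "AB", 0.5, np.where(true_geno == "AA", 0.0, 1.0))
    lrr_mean = np.zeros(n)

    chrom_arr = data["chromosome"].to_numpy()
    pos_arr = data["position"].to_numpy()
    for chrom, start, end, etype, f in _event_layers(spec):
        inside = (chrom_arr == chrom) & (pos_arr >= start) & (pos_arr <= end)
        lrr_mean[inside] = config.lrr_compression * expected_lrr_shift(etype, f)
        het_inside = inside & (true_geno == "AB")
        idx = np.flatnonzero(het_inside)
        if idx.size:
            lo, hi = expected_baf_bands(etype, f, "AB")
            pick_hi = rng.random(idx.size) < 0.5
            baf_mean[idx] = np.where(pick_hi, hi, lo)

    baf = np.clip(baf_mean + rng.normal(0.0, config.baf_noise_sd, size=n), 0.0, 1.0)
    lrr = lrr_mean + rng.normal(0.0, config.lrr_noise_sd, size=n)

    lo_het, hi_het = config.het_call_range
    call = np.full(n, "missing", dtype=object)
    call[baf < config.hom_call_max_baf] = "AA"
    call[baf > 1 - config.hom_call_max_baf] = "BB"
    call[(baf >= lo_het) & (baf <= hi_het)] = "AB"
    call[rng.random(n) < config.missing_rate] = "missing"

    data["genotype"] = call
    data["baf"] = baf
    data["lrr"] = lrr
    return IntensityProfile(subject_id=spec.subject_id, data=data)


def _draw_interval(chrom_spec, size_range, rng) -> tuple[int, int]:
    lo, hi = size_range
    hi = min(hi, chrom_spec.length)
    size = int(np.exp(rng.uniform(np.log(lo), np.log(max(hi, lo + 1)))))
    size = min(size, chrom_spec.length - 1)
    start = int(rng.integers(1, chrom_spec.length - size + 1))
    return start, start + size


def _plant_events(spec: SubjectSpec, genome: GenomeModel, config: CohortConfig, rng) -> None:
    etypes = list(config.event_type_probs)
    eprobs = np.array([config.event_type_probs[t] for t in etypes], dtype=float)
    eprobs /= eprobs.sum()
    n_events = 1 + rng.poisson(config.extra_events_rate)
    used: dict[str, list] = {}
    for _ in range(n_events):
        for _attempt in range(20):
            chrom = genome.chromosomes[rng.integers(len(genome.chromosomes))]
            start, end = _draw_interval(chrom, config.event_size_range, rng)
            if all(end < s or start > e for s, e in used.get(chrom.name, [])):
                break
        else:
            continue
        used.setdefault(chrom.name, []).append((start, end))
        spec.mosaic_events.append(
            MosaicEventSpec(
                chromosome=chrom.name,
                start=start,
                end=end,
                event_type=etypes[rng.choice(len(etypes), p=eprobs)],
                f=float(rng.uniform(*config.f_range)),
            )
        )


def simulate_cohort(
    config: CohortConfig, genome: GenomeModel, manifest: SnpManifest
) -> tuple[list[IntensityProfile], pd.DataFrame, pd.DataFrame]:
    """Generate a full cohort: profiles, ground-truth events, phenotypes.

    Each subject uses an independent RNG stream derived from
    ``(config.seed, subject index)``, so cohorts are reproducible and
    insensitive to generation order. Carrier probability follows
    ``mosaic_prevalence``, optionally modulated by age on the log-odds scale
    (``prevalence_log_or_per_year``).

    Returns ``(profiles, truth, phenotypes)``: ``truth`` has one row per
    planted anomaly (subject_id, chromosome, start, end, event_type, f,
    origin), ``phenotypes`` one row per subject.
    """
    master = np.random.default_rng([config.seed, 0xC0F0])
    mean_age = sum(config.age_range) / 2

    profiles: list[IntensityProfile] = []
    truth_rows = []
    subject_rows = []
    for i in range(config.n_subjects):
        rng = np.random.default_rng([config.seed, 1, i])
        sid = f"S{i:05d}"
        age = float(rng.uniform(*config.age_range))
        cohort = config.cohort_labels[rng.choice(len(config.cohort_labels), p=np.asarray(config.cohort_probs))]
        spec = SubjectSpec(subject_id=sid, age_baseline=age, cohort=cohort)

        p = config.mosaic_prevalence
        if config.prevalence_log_or_per_year != 0.0 and 0 < p < 1:
            logit = np.log(p / (1 - p)) + config.prevalence_log_or_per_year * (age - mean_age)
            p = 1 / (1 + np.exp(-logit))
        if rng.random() < p:
            _plant_events(spec, genome, config, rng)
        if rng.random() < config.cnv_prevalence:
            chrom = genome.chromosomes[rng.integers(len(genome.chromosomes))]
            start, end = _draw_interval(chrom, config.cnv_size_range, rng)
            spec.constitutive_cnvs.append(
                ConstitutiveCnvSpec(chromosome=chrom.name, start=start, end=end, copy_number=3)
            )

        profiles.append(simulate_subject(spec, manifest, config, rng))
        for ev in spec.mosaic_events:
            truth_rows.append(
                (sid, ev.chromosome, ev.start, ev.end, ev.event_type, ev.f, "mosaic")
            )
        for cnv in spec.constitutive_cnvs:
            truth_rows.append(
                (sid, cnv.chromosome, cnv.start, cnv.end,
                 "gain" if cnv.copy_number == 3 else "loss", 1.0, "constitutive")
            )
        subject_rows.append(
            {
                "subject_id": sid,
                "age_baseline": age,
                "cohort": cohort,
                "is_mosaic_carrier": int(bool(spec.mosaic_events)),
            }
        )

    truth = pd.DataFrame(
        truth_rows,
        columns=["subject_id", "chromosome", "start", "end", "event_type", "f", "origin"],
    )
    subjects = pd.DataFrame(subject_rows)
    phenotypes = simulate_survival(subjects, config, master)
    return profiles, truth, phenotypes


def simulate_survival(
    subjects: pd.DataFrame, config: CohortConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw incident-cancer outcomes for a table of subjects.

    Event times are exponential with per-subject rate
    ``baseline_hazard x hr_mosaic^carrier x hr_per_year_age^(age - mean age)``,
    administratively censored at ``max_followup`` years. Diagnosed cases get
    a category from ``diagnosis_probs``; a small fraction of subjects carries
    a prior cancer history flag (they are removed by the incidence filters
    downstream).

    ``subjects`` needs columns subject_id, age_baseline, cohort,
    is_mosaic_carrier.
    """
    n = len(subjects)
    mean_age = sum(config.age_range) / 2
    rate = (
        config.baseline_hazard
        * np.power(config.hr_mosaic, subjects["is_mosaic_carrier"].to_numpy())
        * np.power(config.hr_per_year_age, subjects["age_baseline"].to_numpy() - mean_age)
    )
    t_event = rng.exponential(1.0 / np.maximum(rate, 1e-300), size=n)
    event = (t_event <= config.max_followup).astype(int)
    followup = np.full(n, float(config.max_followup))

    cats = list(config.diagnosis_probs)
    probs = np.array([config.diagnosis_probs[c] for c in cats], dtype=float)
    probs /= probs.sum()
    diag_draw = rng.choice(len(cats), size=n, p=probs)
    diagnosis = np.where(event == 1, np.array(cats, dtype=object)[diag_draw], "none")
    diagnosis_time = np.where(event == 1, t_event, np.nan)
    prior = (rng.random(n) < config.prior_history_rate).astype(int)

    return pd.DataFrame(
        {
            "subject_id": subjects["subject_id"].to_numpy(),
            "age_baseline": subjects["age_baseline"].to_numpy(),
            "cohort": subjects["cohort"].to_numpy(),
            "followup_time": followup,
            "event": event,
            "diagnosis": diagnosis,
            "diagnosis_time": diagnosis_time,
            "prior_history": prior,
        }
    )
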
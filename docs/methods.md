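# Methods

## Signal model

A mosaic anomaly is modeled as a two-population cell mixture: a fraction
*f* ∈ (0, 1] of cells carries the anomaly and the remainder is diploid; only
mixtures with one diploid population are considered (sub-clonal structure
with several aberrant populations is out of scope). At a heterozygous SNP
the B-allele frequency (BAF) is the ratio of mean B-allele copies to mean
total copies across the mixture, which yields two bands symmetric about 0.5
(loss: (1−f)/(2−f) and 1/(2−f); gain: 1/(2+f) and (1+f)/(2+f); CN-LOH:
(1±f)/2). Homozygous SNPs stay pinned at 0 and 1 for every event type —
allele-specific dropout is not modeled — which is also why homozygotes carry
no imbalance signal and detection works on heterozygous/missing loci only.
The log R ratio (LRR) is idealized as log₂(c/2) with c the mean copy number,
so CN-LOH sits at 0, a full monosomy at −1 and a full trisomy at +0.585. An
optional multiplicative compression factor (default 1.0) can emulate the
amplitude compression of real arrays; all thresholds are applied on the same
scale on both the simulation and detection sides, so the default is neutral.

Coordinates are 1-based and inclusive at both ends everywhere (manifests,
anomaly intervals, call tables).

## Synthetic cohorts

The generator (`synthetic_cohort`) emulates the study population the method
was built for: subjects aged 50–89 (uniform), two study cohorts, a mosaic
carrier prevalence of 1.4% by default (optionally age-modulated on the
log-odds scale), an event-type mix of 8% gains / 41.5% losses / 50.5%
CN-LOH, clonal fractions uniform on [0.1, 0.8], and event sizes log-uniform
on 2–30 Mb. Carriers receive 1 + Poisson(0.18) events, matching ~1.2
anomalies per carrier. Constitutive CNVs (prevalence 2%, 1–5 Mb) are
simulated as full-clonal trisomies: germline deletions erase heterozygotes
entirely and are essentially invisible to BAF-driven detection, consistent
with detected constitutive anomalies falling in the trisomic (3N) space.

Noise is Gaussian: BAF SD 0.03 (clean samples then comfortably pass the
0.06 QC bound) and LRR SD 0.08. The LRR default is deliberately below the
0.1 low-quality screen; a higher value would exclude every simulated sample
by construction. The genotype-caller model calls AA below BAF 0.15, BB
above 0.85, AB within [0.35, 0.65] and no-call otherwise, plus a uniform
0.5% no-call rate; hets inside strong anomalies therefore drift out of the
AB zone and go missing, which is exactly why the eligible set for detection
is "heterozygous or missing".

Survival outcomes are exponential with per-subject rate
baseline_hazard × hr_mosaic^carrier × hr_age^(age−mean), administratively
censored at 12 years, with diagnosis categories drawn from the observed
incident-case mix (22.3% leukemia, 52.4% NHL, 2.6% HL, 20.1% MM, 2.6% MDS)
and a 2% prior-history rate. The default baseline hazard (0.0017/yr)
matches the source population's incidence; the survival *benchmark* raises
it to 0.01/yr so that a 2,000-subject replicate carries enough events for
hazard-ratio estimation to be informative (at the population rate a desk-
scale replicate has ~2 exposed events and no estimator is stable).

Every subject has an independent RNG stream derived from (seed, subject
index), so cohorts are reproducible and order-independent.

What the generator does **not** emulate: GC waves and batch effects, array-
specific LRR compression and BAF reference-cluster error, sex chromosomes,
linkage between SNPs (genotypes are i.i.d.), allele-specific dropout, and
multi-clonal mixtures. Passing tests therefore demonstrate correctness of
the algorithmic chain under the stated signal model, not performance on any
particular real array product.

## Detection

At each chromosome the eligible (AB/missing) SNPs are transformed to
tBAF = √min(BAF, 1−BAF, |BAF − median BAF|), with the median taken over the
chromosome's eligible SNPs (chromosome scope shifts the reference least
under a whole-chromosome event; sample scope is available via
configuration). Circular binary segmentation then recursively finds, over
the current segment, the arc maximizing the standardized arc-vs-complement
mean difference (both sides ≥ 5 probes; arcs and their complements give the
same statistic, so only non-wrapping arcs are enumerated) and accepts the
split when its permutation p-value is below α = 0.01 (1,000 seeded
permutations; early termination as soon as the exceedance count fixes
p ≥ α). The exhaustive O(n²) arc scan and the permutation loop are numba
kernels; determinism comes from per-segment seeds derived from the
configured seed and a recursion counter.

Candidate calling iterates a robust baseline: the median tBAF over SNPs in
not-yet-flagged segments, with scale 1.4826 × MAD (floored at 10⁻⁴ for
noiseless data). A segment is flagged when its mean tBAF exceeds the
baseline by ≥ 4 robust standard errors — the MAD-based SD divided by
√n_probes, i.e. a z-test on the segment mean — one-sided, since anomalies
only raise tBAF. The √n scaling is the package's design choice: a fixed
threshold on the *mean*-vs-*SNP-level* scale cannot simultaneously keep the
null false-call rate near zero and detect moderate-f events, whereas the
standard-error form does both with a single z = 4 default. Flagged
segments spanning ≥ 50 kb become candidates.

## Filtering

Fixed order: sample screen → merge → centromere resolution → probe filter;
the anomaly-level stages are idempotent. The low-quality screen excludes
samples with non-anomalous BAF or LRR SD > 0.1 or with oversegmentation:
spurious change-points per eligible SNP, where each called anomaly is
allowed its two change-points and a clean chromosome its single segment
(excess = max(0, segments − 1 − 2 × called anomalies)), against the
per-chromosome (8×10⁻⁴) and genome-wide (10⁻⁴) thresholds. Counting raw
segments would flag every sample (each autosome contributes one segment),
so the screen targets what it is for: segmentation noise.

Adjacent candidates closer than 300 eligible probes with mean LRR within
0.05 are merged left-to-right to a fixpoint; merged metrics are recomputed
over the union *including* the gap probes. A candidate spanning the
centromere is kept intact only with ≥ 500 eligible probes on each arm,
otherwise split at the centromere with each part re-evaluated. Anomalies
need ≥ 50 eligible probes. Anomalies over 2 Mb are additionally exported to
a review queue — the deterministic stand-in for manual visual review.

## Classification

Each anomaly is summarized by LRR deviation (median LRR inside minus
median outside, all probes) and BAF MAD (median |BAF − non-anomalous median
BAF| over eligible probes inside); the non-anomalous background is the same
chromosome outside all its anomalies, falling back to genome-wide probes
(flagged) when none remain. k-means (k = 3, 20 seeded restarts) on
z-scored metrics locates the constitutive cloud, identified as the centroid
nearest the theoretical trisomy signature (log₂(3/2), 1/6) in standardized
units — the constitutive cluster is by definition the one in 3N space, and
this identification stays correct even when high-f mosaic CN-LOH clusters
exceed the trisomic BAF MAD. Anomalies within two MAD radii of that
cluster's median (median Euclidean distance scaled by 1.4826, so the MAD
acts as a robust SD and ~95% of a Gaussian cluster falls inside) are
constitutive; all others mosaic. With fewer than three anomalies no model
is fitted and everything is treated as putatively mosaic. Clustering pools
anomalies across cohorts.

Mosaic anomalies get a CN state from the LRR deviation: gain above +0.05,
loss below −0.05, CN-LOH inside the closed band (the boundary ±0.05 itself
is CN-LOH, following the strict gain/loss inequalities). The clonal
fraction estimate inverts the band offset Δ = BAF MAD: f = 2Δ (CN-LOH),
4Δ/(1+2Δ) (loss), 4Δ/(1−2Δ) (gain), clipped to [0, 1]. Location typing is
purely positional: an interval reaching a SNP within 3 probes of a
chromosome's terminal manifest SNP "reaches" that end; both ends → whole,
one → p/q terminal, neither → interstitial (the 3-probe tolerance reflects
segmentation endpoint uncertainty of tens of kilobases). Events are
"large" strictly above 2 Mb.

## Association

Incidence filters exclude prior cancer history, missing history, diagnosis
inside the first follow-up year, and under one year of follow-up; survival
time is diagnosis time for cases, follow-up time otherwise. Cox fits use
the Efron tie correction, robust (sandwich) variance grouped by subject,
age in years entered linearly, and cohort as indicator contrasts against
the largest cohort. Rare binary exposures make lifelines' default Newton
step overshoot, so fits use a 0.5 step with a 0.25/0.1 retry ladder. The
2×2 test is the two-sided exact test by hypergeometric enumeration
(tables as improbable as observed, with the usual 1+10⁻⁷ tie guard).
Percentages print with one decimal, round-half-to-even.

## Benchmarks (`validation`)

Problem sizes are chosen for a single-CPU workstation: detection uses one
70 Mb chromosome at 60 SNPs/Mb (~1,400 eligible probes) with a 21 Mb
planted CN-LOH event at f = 0.3 (~420 eligible probes), 100 event and 200
null replicates; classification uses 30 anomalies per mosaic event type
over f ∈ [0.1, 0.8] plus 30 trisomies, with anomaly intervals taken from
the simulator truth so the scores isolate the classification stage;
survival uses n = 2,000, 1.5% carriers, 200 replicates per generating
hazard ratio in {3, 5, 10, 20}. CN-state accuracy is reported for f ≥ 0.2
because below that the gain/loss LRR shift (≤ 0.07) approaches the ±0.05
classification band and the state is not identifiable by design.

## Known limitations

* Balanced rearrangements produce no BAF/LRR signature and are
  undetectable by construction.
* Detection sensitivity decays for f below ~0.1 (bands within noise of
  0.5) and for events with few eligible probes; the 50-probe and 50-kb
  floors are hard limits.
* Germline deletions are largely invisible to the BAF-driven detector
  (no heterozygotes inside), so the constitutive class is in practice the
  trisomic cloud.
* The printed oversegmentation thresholds were calibrated for ~10⁵
  eligible SNPs per sample; at the scaled-down synthetic array sizes the
  screen depends on the excess-change-point correction described above.
* k-means constitutive identification assumes at least a handful of
  anomalies per cohort; tiny cohorts fall back to flag-everything-mosaic
  or produce unstable splits (see the worked example in the README).
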
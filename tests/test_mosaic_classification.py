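import numpy as np
import pytest

from mosaicscan.baf_segmentation import CandidateAnomaly, Segment, build_tbaf_series
from mosaicscan.genome_model import ChromosomeSpec, GenomeModel, generate_manifest
from mosaicscan.mosaic_classification import (
    AnomalyMetrics,
    classify_event,
    cluster_anomalies,
    compute_metrics,
    estimate_mosaic_fraction,
    finalize_calls,
    flag_constitutive,
)
from mosaicscan.synthetic_cohort import (
    CohortConfig,
    MosaicEventSpec,
    SubjectSpec,
    simulate_subject,
)


@pytest.fixture(scope="module")
def sim():
    g = GenomeModel((ChromosomeSpec("chr1", 40_000_000, 18_000_000, 19_000_000),))
    return g, generate_manifest(g, 60.0, seed=21)


def truth_candidate(series, start, end, subject="S"):
    lo = int(np.searchsorted(series.position, start))
    hi = int(np.searchsorted(series.position, end, side="right")) - 1
    seg = Segment(
        chromosome=series.chromosome, start_index=lo, end_index=hi,
        start_pos=int(series.position[lo]), end_pos=int(series.position[hi]),
        n_probes=hi - lo + 1,
        mean_tbaf=float(np.mean(series.tbaf[lo: hi + 1])),
        mean_lrr=float(np.mean(series.lrr[lo: hi + 1])),
    )
    return CandidateAnomaly(subject, seg, 10.0, 0.1, 0.05)


def metrics_for_event(sim, etype, f, seed, noiseless=True, missing_rate=0.0):
    genome, manifest = sim
    cfg = CohortConfig(
        baf_noise_sd=0.0 if noiseless else 0.03,
        lrr_noise_sd=0.0 if noiseless else 0.08,
        missing_rate=missing_rate,
        seed=seed,
    )
    ev = MosaicEventSpec("chr1", 20_000_000, 38_000_000, etype, f)
    spec = SubjectSpec("S", 70.0, "sim", mosaic_events=[ev])
    prof = simulate_subject(spec, manifest, cfg, np.random.default_rng(seed))
    series = build_tbaf_series(prof, "chr1")
    cand = truth_candidate(series, ev.start, ev.end)
    return compute_metrics(cand, prof, [cand]), cand, prof


class TestComputeMetrics:
    def test_noiseless_cnloh(self, sim):
        m, _, _ = metrics_for_event(sim, "cnloh", 0.4, seed=1)
        assert m.lrr_dev == pytest.approx(0.0, abs=1e-9)
        assert m.baf_mad == pytest.approx(0.2, abs=1e-9)

    def test_noiseless_full_monosomy(self, sim):
        """At f=1 a loss removes hets entirely; randomly-missing homozygote
        probes carry BAF 0/1, half a unit from the diploid median."""
        m, _, _ = metrics_for_event(sim, "loss", 1.0, seed=2, missing_rate=0.1)
        assert m.lrr_dev == pytest.approx(-1.0, abs=1e-9)
        assert m.baf_mad == pytest.approx(0.5, abs=1e-9)

    def test_background_anomaly_near_zero(self, sim):
        genome, manifest = sim
        cfg = CohortConfig(baf_noise_sd=0.0, lrr_noise_sd=0.0, missing_rate=0.0, seed=3)
        prof = simulate_subject(
            SubjectSpec("S", 70.0, "sim"), manifest, cfg, np.random.default_rng(3)
        )
        series = build_tbaf_series(prof, "chr1")
        cand = truth_candidate(series, 20_000_000, 38_000_000)
        m = compute_metrics(cand, prof, [cand])
        assert m.lrr_dev == pytest.approx(0.0, abs=1e-9)
        assert m.baf_mad == pytest.approx(0.0, abs=1e-9)

    def test_metrics_validation(self):
        with pytest.raises(ValueError):
            AnomalyMetrics(lrr_dev=0.0, baf_mad=-0.1, n_probes=10, length_bp=100)


def _metric(lrr, mad):
    return AnomalyMetrics(lrr_dev=lrr, baf_mad=mad, n_probes=100, length_bp=1_000_000)


class TestClustering:
    def _separable(self, seed=0):
        rng = np.random.default_rng(seed)
        const = [
            _metric(rng.normal(0.585, 0.01), rng.normal(1 / 6, 0.005)) for _ in range(30)
        ]
        mosaic = [
            _metric(rng.uniform(-0.1, 0.1), rng.uniform(0.02, 0.10)) for _ in range(10)
        ]
        return const + mosaic

    def test_constitutive_cloud_identified(self):
        """The tight trisomy-signature cloud is picked as constitutive; the
        spread low-deviation points stay mosaic. The two-MAD radius keeps
        most (not all) of a Gaussian cloud, so allow its natural ~6% tail."""
        metrics = self._separable()
        model = cluster_anomalies(metrics, seed=1)
        flags = [flag_constitutive(m, model) for m in metrics]
        assert sum(f == "constitutive" for f in flags[:30]) >= 27
        assert flags[30:] == ["mosaic"] * 10

    def test_degenerate_identical_points_all_constitutive(self):
        metrics = [_metric(0.585, 1 / 6)] * 5
        model = cluster_anomalies(metrics, seed=0)
        assert all(flag_constitutive(m, model) == "constitutive" for m in metrics)

    def test_seeded_clustering_reproducible(self):
        metrics = self._separable(3)
        m1 = cluster_anomalies(metrics, seed=5)
        m2 = cluster_anomalies(metrics, seed=5)
        assert np.array_equal(m1.labels, m2.labels)
        assert m1.constitutive_cluster == m2.constitutive_cluster

    def test_fewer_than_three_all_mosaic(self):
        metrics = [_metric(0.0, 0.1), _metric(0.1, 0.2)]
        model = cluster_anomalies(metrics, seed=0)
        assert model.constitutive_cluster is None
        assert all(flag_constitutive(m, model) == "mosaic" for m in metrics)

    def test_far_point_is_mosaic(self):
        metrics = self._separable()
        model = cluster_anomalies(metrics, seed=1)
        assert flag_constitutive(_metric(-1.0, 0.5), model) == "mosaic"


class TestClassifyEvent:
    @pytest.mark.parametrize(
        "lrr_dev,expected",
        [(-0.20, "loss"), (0.20, "gain"), (0.01, "cnloh"), (0.05, "cnloh"), (-0.05, "cnloh")],
    )
    def test_threshold_rule(self, lrr_dev, expected):
        assert classify_event(_metric(lrr_dev, 0.1)) == expected


class TestEstimateFraction:
    @pytest.mark.parametrize(
        "etype,mad,expected",
        [("cnloh", 0.0, 0.0), ("cnloh", 0.15, 0.30), ("loss", 0.0556, 0.20), ("gain", 0.1, 0.5)],
    )
    def test_known_inversions(self, etype, mad, expected):
        assert estimate_mosaic_fraction(etype, mad) == pytest.approx(expected, abs=2e-3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            estimate_mosaic_fraction("cnloh", 0.6)
        with pytest.raises(ValueError):
            estimate_mosaic_fraction("gain", 0.5)

    @pytest.mark.parametrize("etype", ["gain", "loss", "cnloh"])
    def test_noiseless_round_trip(self, sim, etype):
        """Forward-simulated events invert to within 0.01 of the planted f."""
        for f in (0.1, 0.3, 0.5, 0.7):
            m, _, _ = metrics_for_event(sim, etype, f, seed=int(f * 100))
            f_hat = estimate_mosaic_fraction(etype, m.baf_mad)
            assert abs(f_hat - f) <= 0.01


class TestFinalizeCalls:
    def test_large_flag_strictly_above_two_mb(self, sim):
        genome, manifest = sim
        cfg = CohortConfig(baf_noise_sd=0.0, lrr_noise_sd=0.0, missing_rate=0.0, seed=4)
        ev = MosaicEventSpec("chr1", 20_000_000, 30_000_000, "cnloh", 0.4)
        prof = simulate_subject(
            SubjectSpec("S", 70.0, "sim", mosaic_events=[ev]),
            manifest, cfg, np.random.default_rng(4),
        )
        series = build_tbaf_series(prof, "chr1")
        cand = truth_candidate(series, ev.start, ev.end)
        m = compute_metrics(cand, prof, [cand])
        model = cluster_anomalies([m, m, m], seed=0)

        # exactly 2.0 Mb is not "large"; the planted 10 Mb event is
        seg = cand.segment
        short = CandidateAnomaly(
            "S",
            Segment(
                seg.chromosome, seg.start_index, seg.end_index,
                20_000_001, 22_000_000, seg.n_probes, seg.mean_tbaf, seg.mean_lrr,
            ),
            10.0, 0.1, 0.05,
        )
        calls = finalize_calls([cand, short], [m, m], model, manifest, genome)
        assert calls.loc[0, "is_large"] == True  # noqa: E712
        assert calls.loc[1, "is_large"] == False  # noqa: E712

    def test_constitutive_calls_have_no_event_type(self, sim):
        genome, manifest = sim
        metrics = [_metric(0.585, 1 / 6)] * 5
        series_pos = manifest.positions("chr1")
        seg = Segment("chr1", 0, 99, int(series_pos[0]), int(series_pos[99]), 100, 0.4, 0.585)
        anoms = [CandidateAnomaly(f"S{i}", seg, 10.0, 0.1, 0.05) for i in range(5)]
        model = cluster_anomalies(metrics, seed=0)
        calls = finalize_calls(anoms, metrics, model, manifest, genome)
        assert (calls["class"] == "constitutive").all()
        assert (calls["event_type"] == "").all()
        assert calls["f_hat"].isna().all()
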
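import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact

from conftest import cox_grid_oracle, fisher_enumeration_oracle
from mosaicscan.association_analysis import (
    add_margins,
    apply_incidence_filters,
    attach_exposure,
    build_report_tables,
    carrier_percent,
    event_type_percentages,
    fit_cox,
    frequency_by_age_bin,
    km_curve,
    location_percentages,
    two_by_two_test,
)


def make_phenotypes(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id", "age_baseline", "cohort", "followup_time",
            "event", "diagnosis", "diagnosis_time", "prior_history",
        ],
    )


class TestIncidenceFilters:
    def test_exclusion_rules(self):
        ph = make_phenotypes(
            [
                ("early", 70, "c", 10.0, 1, "leukemia", 0.5, 0),
                ("prior", 70, "c", 10.0, 0, "none", np.nan, 1),
                ("short", 70, "c", 0.8, 0, "none", np.nan, 0),
                ("nohist", 70, "c", 10.0, 0, "none", np.nan, np.nan),
                ("keep_event", 70, "c", 10.0, 1, "NHL", 5.0, 0),
                ("keep_censor", 70, "c", 10.0, 0, "none", np.nan, 0),
            ]
        )
        records, log = apply_incidence_filters(ph)
        assert set(records["subject_id"]) == {"keep_event", "keep_censor"}
        reasons = dict(zip(log["subject_id"], log["exclusion_reason"]))
        assert reasons["early"] == "early_diagnosis"
        assert reasons["prior"] == "prior_history"
        assert reasons["short"] == "short_followup"
        assert reasons["nohist"] == "missing_history"

    def test_survival_time_selection(self):
        ph = make_phenotypes(
            [
                ("ev", 70, "c", 10.0, 1, "MM", 5.0, 0),
                ("cen", 70, "c", 9.0, 0, "none", np.nan, 0),
            ]
        )
        records, _ = apply_incidence_filters(ph)
        t = dict(zip(records["subject_id"], records["time"]))
        assert t["ev"] == 5.0 and t["cen"] == 9.0


def toy_records():
    # 6 subjects, distinct event times, binary exposure
    return pd.DataFrame(
        {
            "subject_id": list("abcdef"),
            "time": [2.0, 3.5, 5.0, 6.5, 8.0, 10.0],
            "event": [1, 1, 0, 1, 1, 0],
            "exposure": [1, 1, 0, 0, 1, 0],
            "age_baseline": [60.0] * 6,
            "cohort": ["x"] * 6,
            "diagnosis": ["leukemia", "NHL", "none", "MM", "NHL", "none"],
        }
    )


class TestCox:
    def test_toy_fit_matches_partial_likelihood_grid_oracle(self):
        rec = toy_records()
        fit = fit_cox(rec, "exposure", covariates=())
        beta_grid = cox_grid_oracle(rec["time"], rec["event"], rec["exposure"])
        assert abs(fit.log_hr - beta_grid) < 1e-3
        assert fit.hr == pytest.approx(np.exp(fit.log_hr))
        assert fit.ci95[0] == pytest.approx(np.exp(fit.log_hr - 1.96 * fit.robust_se))

    def test_time_rescaling_invariance(self):
        rec = toy_records()
        fit1 = fit_cox(rec, "exposure", covariates=())
        rec2 = rec.assign(time=rec["time"] * 37.0)
        fit2 = fit_cox(rec2, "exposure", covariates=())
        assert fit1.log_hr == pytest.approx(fit2.log_hr, abs=1e-8)

    def test_degenerate_inputs_rejected(self):
        rec = toy_records()
        with pytest.raises(ValueError, match="vary"):
            fit_cox(rec.assign(exposure=1), "exposure", covariates=())
        with pytest.raises(ValueError, match="events"):
            fit_cox(rec.assign(event=0), "exposure", covariates=())

    def test_cohort_indicator_adjustment_runs(self):
        rng = np.random.default_rng(0)
        n = 400
        rec = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "time": rng.exponential(10, n),
                "event": rng.integers(0, 2, n),
                "exposure": rng.integers(0, 2, n),
                "age_baseline": rng.uniform(50, 89, n),
                "cohort": rng.choice(["a", "b", "c"], n),
            }
        )
        fit = fit_cox(rec, "exposure")
        assert np.isfinite(fit.log_hr) and np.isfinite(fit.p_value)
        # two indicator contrasts for three cohorts, plus age and exposure
        assert len(fit.covariates) == 4


class TestKaplanMeier:
    def test_hand_computed_product_limit(self):
        rec = pd.DataFrame(
            {
                "time": [1.0, 2.0, 3.0, 4.0, 5.0],
                "event": [1, 0, 1, 1, 0],
                "grp": ["g"] * 5,
            }
        )
        curve = km_curve(rec, "grp")["g"]
        surv = dict(zip(curve["time"], curve["survival"]))
        assert surv[1.0] == pytest.approx(4 / 5)
        assert surv[3.0] == pytest.approx(4 / 5 * 2 / 3)
        assert surv[4.0] == pytest.approx(4 / 5 * 2 / 3 * 1 / 2)

    def test_no_events_flat_at_one(self):
        rec = pd.DataFrame({"time": [1.0, 2.0], "event": [0, 0], "grp": ["g", "g"]})
        curve = km_curve(rec, "grp")["g"]
        assert (curve["survival"] == 1.0).all()

    def test_all_distinct_events_step_heights(self):
        n = 5
        rec = pd.DataFrame(
            {"time": np.arange(1, n + 1, dtype=float), "event": [1] * n, "grp": ["g"] * n}
        )
        curve = km_curve(rec, "grp")["g"]
        surv = curve.loc[curve["time"] > 0, "survival"].to_numpy()
        assert np.allclose(surv, 1 - np.arange(1, n + 1) / n)


class TestTwoByTwo:
    def test_matches_enumeration_oracle_exactly(self):
        for table in [(2, 3, 4, 1), (0, 5, 5, 0), (3, 3, 3, 3), (1, 9, 8, 2)]:
            assert two_by_two_test(*table) == pytest.approx(
                fisher_enumeration_oracle(*table), abs=1e-12
            )

    def test_equal_proportions_give_one(self):
        assert two_by_two_test(5, 5, 5, 5) == pytest.approx(1.0)

    def test_agrees_with_scipy_fisher(self):
        for table in [(9, 42, 7, 170), (2, 8, 11, 3)]:
            _, p = fisher_exact([[table[0], table[1]], [table[2], table[3]]])
            assert two_by_two_test(*table) == pytest.approx(p, rel=1e-9)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            two_by_two_test(0, 0, 3, 4)


class TestFrequencyByAgeBin:
    def test_left_closed_bins_and_percent(self):
        subj = pd.DataFrame(
            {"age_baseline": [50.0, 54.9, 55.0, 62.0], "is_mosaic_carrier": [1, 0, 1, 1]}
        )
        table = frequency_by_age_bin(subj)
        by_start = table.set_index("bin_start")
        assert by_start.loc[50.0, "n"] == 2 and by_start.loc[50.0, "percent"] == 50.0
        assert by_start.loc[55.0, "n"] == 1 and by_start.loc[55.0, "percent"] == 100.0
        assert by_start.loc[60.0, "percent"] == 100.0

    def test_empty_bin_blank_percent(self):
        subj = pd.DataFrame({"age_baseline": [50.0, 61.0], "is_mosaic_carrier": [0, 0]})
        table = frequency_by_age_bin(subj).set_index("bin_start")
        assert table.loc[55.0, "n"] == 0 and np.isnan(table.loc[55.0, "percent"])

    def test_age_trend_recovered_from_generator(self):
        """A cohort generated with rising carrier odds by age shows a
        monotone carrier frequency across age tertiles."""
        rng = np.random.default_rng(8)
        age = rng.uniform(50, 89, 6000)
        logit = np.log(0.05 / 0.95) + 0.08 * (age - 69.5)
        carrier = rng.random(6000) < 1 / (1 + np.exp(-logit))
        subj = pd.DataFrame({"age_baseline": age, "is_mosaic_carrier": carrier.astype(int)})
        table = frequency_by_age_bin(subj, bin_width=13.0)
        pct = table.loc[table["n"] > 0, "percent"].to_numpy()
        assert np.all(np.diff(pct) > 0)


class TestReportTables:
    def test_percentages_from_published_cross_tab(self):
        """The published cross-tab of 200 mosaic anomalies reproduces the
        event-type shares 8.0 / 41.5 / 50.5 and location shares 6.5 / 60.0."""
        counts = add_margins(
            pd.DataFrame(
                {"gain": [8, 0, 1, 7], "loss": [0, 3, 2, 78], "cnloh": [5, 26, 35, 35]},
                index=["whole", "p_terminal", "q_terminal", "interstitial"],
            )
        )
        assert counts.loc["All", "All"] == 200
        pct = event_type_percentages(counts)
        assert (pct["gain"], pct["loss"], pct["cnloh"]) == (8.0, 41.5, 50.5)
        loc = location_percentages(counts)
        assert loc["whole"] == 6.5 and loc["interstitial"] == 60.0

    def test_carrier_percent_rounding(self):
        assert carrier_percent(9, 51) == 17.6
        assert carrier_percent(16, 229) == 7.0
        assert carrier_percent(153, 11947) == 1.3
        assert carrier_percent(169, 12176) == 1.4
        assert carrier_percent(117, 12176) == 1.0

    def test_empty_calls_give_zero_table(self):
        calls = pd.DataFrame(
            columns=["subject_id", "class", "event_type", "location", "is_large"]
        )
        rec = toy_records()
        rec = attach_exposure(rec, calls)
        tables = build_report_tables(calls, rec)
        assert tables["location_event"].loc["All", "All"] == 0
        assert tables["cohort_summary"]["pct_mosaic_carriers"] == 0.0

    def test_exposure_attachment(self):
        calls = pd.DataFrame(
            {
                "subject_id": ["a", "b", "z"],
                "class": ["mosaic", "constitutive", "mosaic"],
                "event_type": ["loss", "", "gain"],
                "location": ["interstitial"] * 3,
                "is_large": [True, True, False],
            }
        )
        rec = attach_exposure(toy_records(), calls)
        flags = rec.set_index("subject_id")
        assert flags.loc["a", "exposure_any_mosaic"] == 1
        assert flags.loc["a", "exposure_large_mosaic"] == 1
        assert flags.loc["b", "exposure_any_mosaic"] == 0  # constitutive ignored
        assert flags.loc["c", "exposure_any_mosaic"] == 0
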
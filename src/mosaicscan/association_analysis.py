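"""Survival association between detected mosaicism and incident hematologic
cancer: incidence filtering, Cox proportional hazards with robust variance,
Kaplan-Meier curves, exact contingency tests, and summary tables.

The exposure is carriage of a detected mosaic anomaly (or, for the
leukemia analysis, of a large one, >2 Mb), fixed at baseline. Fits adjust
for age at baseline (linear, years) and study cohort (indicator contrasts,
largest cohort as reference) and report the sandwich variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from scipy.stats import hypergeom

__all__ = [
    "CoxFit",
    "apply_incidence_filters",
    "attach_exposure",
    "fit_cox",
    "km_curve",
    "two_by_two_test",
    "frequency_by_age_bin",
    "location_event_table",
    "event_type_percentages",
    "location_percentages",
    "carrier_percent",
    "build_report_tables",
]

LOCATIONS = ("whole", "p_terminal", "q_terminal", "interstitial")
EVENT_COLS = ("gain", "loss", "cnloh")


@dataclass(frozen=True)
class CoxFit:
    log_hr: float
    hr: float
    robust_se: float
    ci95: tuple
    p_value: float
    n: int
    n_events: int
    covariates: pd.DataFrame  # full coefficient table


def apply_incidence_filters(
    phenotypes: pd.DataFrame, min_followup: float = 1.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict to subjects eligible for incidence analysis.

    Excluded (with reasons logged): prior cancer history, missing history,
    diagnosis within the first ``min_followup`` years, or less than
    ``min_followup`` years of follow-up. Survival time becomes
    diagnosis_time for events and followup_time for censored subjects.
    Returns (records, exclusion_log).
    """
    df = phenotypes.copy()
    reasons = pd.Series("", index=df.index, dtype=object)

    def add_reason(mask, code):
        reasons[mask] = np.where(reasons[mask] == "", code, reasons[mask] + ";" + code)

    hist = df["prior_history"]
    add_reason(hist.isna(), "missing_history")
    add_reason(hist.fillna(0).astype(float) == 1, "prior_history")
    is_event = df["event"].fillna(0).astype(int) == 1
    add_reason(is_event & (df["diagnosis_time"] < min_followup), "early_diagnosis")
    add_reason(df["followup_time"] < min_followup, "short_followup")
    bad_time = is_event & df["diagnosis_time"].isna()
    add_reason(bad_time, "malformed_record")

    excluded = df.loc[reasons != ""].copy()
    excluded["exclusion_reason"] = reasons[reasons != ""]
    kept = df.loc[reasons == ""].copy()
    kept["time"] = np.where(kept["event"] == 1, kept["diagnosis_time"], kept["followup_time"])
    records = kept[
        ["subject_id", "time", "event", "diagnosis", "age_baseline", "cohort"]
    ].reset_index(drop=True)
    log = excluded[["subject_id", "exclusion_reason"]].reset_index(drop=True)
    return records, log


def attach_exposure(records: pd.DataFrame, calls: pd.DataFrame) -> pd.DataFrame:
    """Add exposure flags from a final call table (mosaic class only)."""
    mosaic = calls[calls["class"] == "mosaic"] if len(calls) else calls
    any_carriers = set(mosaic["subject_id"]) if len(mosaic) else set()
    large_carriers = (
        set(mosaic.loc[mosaic["is_large"], "subject_id"]) if len(mosaic) else set()
    )
    out = records.copy()
    out["exposure_any_mosaic"] = out["subject_id"].isin(any_carriers).astype(int)
    out["exposure_large_mosaic"] = out["subject_id"].isin(large_carriers).astype(int)
    return out


def fit_cox(
    records: pd.DataFrame,
    exposure: str,
    covariates: tuple = ("age_baseline", "cohort"),
    robust: bool = True,
) -> CoxFit:
    """Cox proportional-hazards fit for a binary exposure.

    Uses the Efron tie correction and, by default, the robust sandwich
    variance. Categorical covariates are expanded to indicator contrasts
    with the largest level as reference.
    """
    if records["event"].sum() == 0:
        raise ValueError("no events in the data")
    if records[exposure].nunique() < 2:
        raise ValueError(f"exposure {exposure!r} does not vary")

    cols = {exposure: records[exposure].astype(float)}
    for cov in covariates:
        vals = records[cov]
        if vals.dtype == object or isinstance(vals.dtype, pd.CategoricalDtype):
            ref = vals.value_counts().idxmax()
            for level in sorted(v for v in vals.unique() if v != ref):
                cols[f"{cov}_{level}"] = (vals == level).astype(float)
        else:
            cols[cov] = vals.astype(float)
    df = pd.DataFrame(cols)
    df["time"] = records["time"].to_numpy()
    df["event"] = records["event"].to_numpy()

    # rare binary exposures overshoot at lifelines' default Newton step
    cph = CoxPHFitter()
    last_err = None
    for step_size in (0.5, 0.25, 0.1):
        try:
            cph.fit(
                df, duration_col="time", event_col="event", robust=robust,
                fit_options={"step_size": step_size},
            )
            break
        except ConvergenceError as err:
            last_err = err
    else:
        raise last_err
    summ = cph.summary
    row = summ.loc[exposure]
    log_hr = float(row["coef"])
    se = float(row["se(coef)"])
    return CoxFit(
        log_hr=log_hr,
        hr=float(np.exp(log_hr)),
        robust_se=se,
        ci95=(float(np.exp(log_hr - 1.96 * se)), float(np.exp(log_hr + 1.96 * se))),
        p_value=float(row["p"]),
        n=len(df),
        n_events=int(df["event"].sum()),
        covariates=summ,
    )


def km_curve(records: pd.DataFrame, stratum: str) -> dict[str, pd.DataFrame]:
    """Kaplan-Meier product-limit curves per stratum.

    Returns, per stratum value, a frame of (time, survival, at_risk).
    Empty strata are omitted.
    """
    out = {}
    for value, grp in records.groupby(stratum):
        if grp.empty:
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(grp["time"], event_observed=grp["event"])
        table = kmf.event_table
        surv = kmf.survival_function_["KM_estimate"]
        out[value] = pd.DataFrame(
            {
                "time": surv.index.to_numpy(dtype=float),
                "survival": surv.to_numpy(dtype=float),
                "at_risk": table["at_risk"].reindex(surv.index).to_numpy(dtype=float),
            }
        ).reset_index(drop=True)
    return out


def two_by_two_test(a: int, b: int, c: int, d: int) -> float:
    """Two-sided exact p-value for a 2x2 table by hypergeometric enumeration.

    Table layout: rows are groups (a+b, c+d), columns outcomes. All tables
    with the observed margins are enumerated; those whose probability does
    not exceed the observed table's (within a 1e-7 relative tolerance, the
    usual guard against floating-point ties) contribute to the p-value.
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("counts must be non-negative")
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        raise ValueError("both margins must be positive")
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, r1, c1)
    p_obs = hypergeom.pmf(a, n, r1, c1)
    return float(np.minimum(pmf[pmf <= p_obs * (1 + 1e-7)].sum(), 1.0))


def frequency_by_age_bin(
    subjects: pd.DataFrame, carrier_col: str = "is_mosaic_carrier", bin_width: float = 5.0
) -> pd.DataFrame:
    """Carrier frequency across left-closed age bins [50, 55), [55, 60), ...

    Returns (bin_start, bin_end, n, carriers, percent); percent is blank
    (NaN) for empty bins.
    """
    ages = subjects["age_baseline"].to_numpy(dtype=float)
    if len(ages) == 0:
        return pd.DataFrame(columns=["bin_start", "bin_end", "n", "carriers", "percent"])
    lo = np.floor(ages.min() / bin_width) * bin_width
    hi = np.floor(ages.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    rows = []
    for start, end in zip(edges[:-1], edges[1:]):
        mask = (ages >= start) & (ages < end)
        n = int(mask.sum())
        carriers = int(subjects.loc[mask, carrier_col].sum()) if n else 0
        rows.append(
            {
                "bin_start": start,
                "bin_end": end,
                "n": n,
                "carriers": carriers,
                "percent": round(100.0 * carriers / n, 1) if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


def add_margins(counts: pd.DataFrame) -> pd.DataFrame:
    """Append All row/column sums to a location x event-type count table."""
    table = counts.copy()
    table["All"] = table.sum(axis=1)
    table.loc["All"] = table.sum(axis=0)
    return table


def location_event_table(calls: pd.DataFrame) -> pd.DataFrame:
    """Counts of mosaic anomalies by location (rows) and event type (columns),
    with All margins."""
    mosaic = calls[calls["class"] == "mosaic"] if len(calls) else calls
    table = pd.DataFrame(0, index=list(LOCATIONS), columns=list(EVENT_COLS))
    if len(mosaic):
        ct = pd.crosstab(mosaic["location"], mosaic["event_type"])
        for loc in table.index:
            for ev in table.columns:
                if loc in ct.index and ev in ct.columns:
                    table.loc[loc, ev] = int(ct.loc[loc, ev])
    return add_margins(table)


def event_type_percentages(counts: pd.DataFrame) -> dict[str, float]:
    """Share of anomalies per event type, one decimal, round-half-to-even."""
    total = counts.loc["All", "All"]
    if total == 0:
        return {ev: 0.0 for ev in EVENT_COLS}
    return {ev: round(100.0 * counts.loc["All", ev] / total, 1) for ev in EVENT_COLS}


def location_percentages(counts: pd.DataFrame) -> dict[str, float]:
    total = counts.loc["All", "All"]
    if total == 0:
        return {loc: 0.0 for loc in LOCATIONS}
    return {loc: round(100.0 * counts.loc[loc, "All"] / total, 1) for loc in LOCATIONS}


def carrier_percent(n_carriers: int, n_total: int) -> float:
    """Carrier frequency as a percentage, one decimal, round-half-to-even."""
    if n_total == 0:
        raise ValueError("n_total must be positive")
    return round(100.0 * n_carriers / n_total, 1)


def build_report_tables(calls: pd.DataFrame, records: pd.DataFrame) -> dict:
    """Assemble the summary tables of the analysis.

    * ``location_event`` — counts by location x event type with margins,
      plus ``event_type_pct`` and ``location_pct``;
    * ``per_diagnosis`` — per diagnosis category: N, mosaic carriers n (%),
      non-mosaic n (%);
    * ``hazard_ratios`` — any-mosaic/all-cancer and large-mosaic/leukemia
      Cox fits (rows omitted when a fit is impossible, e.g. no events);
    * ``cohort_summary`` — carrier percentages over the record set.

    ``records`` must already carry exposure flags (see ``attach_exposure``).
    """
    tables: dict = {}
    counts = location_event_table(calls)
    tables["location_event"] = counts
    tables["event_type_pct"] = event_type_percentages(counts)
    tables["location_pct"] = location_percentages(counts)

    rows = []
    diag_order = [d for d in records["diagnosis"].unique() if d != "none"]
    for diag in list(diag_order) + ["none"]:
        grp = records[records["diagnosis"] == diag]
        if grp.empty:
            continue
        n = len(grp)
        mos = int(grp["exposure_any_mosaic"].sum())
        rows.append(
            {
                "diagnosis": diag if diag != "none" else "no_hematologic_cancer",
                "n": n,
                "mosaic_n": mos,
                "mosaic_pct": carrier_percent(mos, n),
                "non_mosaic_n": n - mos,
                "non_mosaic_pct": carrier_percent(n - mos, n),
            }
        )
    cases = records[records["diagnosis"] != "none"]
    if len(cases):
        mos = int(cases["exposure_any_mosaic"].sum())
        rows.append(
            {
                "diagnosis": "all_cases",
                "n": len(cases),
                "mosaic_n": mos,
                "mosaic_pct": carrier_percent(mos, len(cases)),
                "non_mosaic_n": len(cases) - mos,
                "non_mosaic_pct": carrier_percent(len(cases) - mos, len(cases)),
            }
        )
    tables["per_diagnosis"] = pd.DataFrame(rows)

    hr_rows = []
    try:
        fit = fit_cox(records, "exposure_any_mosaic")
        hr_rows.append(
            {
                "outcome": "hematologic_cancer", "exposure": "any_mosaic",
                "n_cases": int(records["event"].sum()), "hr": fit.hr,
                "ci_low": fit.ci95[0], "ci_high": fit.ci95[1], "p_value": fit.p_value,
            }
        )
    except (ValueError, KeyError):
        pass
    leuk = records.copy()
    leuk["event"] = ((records["event"] == 1) & (records["diagnosis"] == "leukemia")).astype(int)
    try:
        fit = fit_cox(leuk, "exposure_large_mosaic")
        hr_rows.append(
            {
                "outcome": "leukemia", "exposure": "large_mosaic",
                "n_cases": int(leuk["event"].sum()), "hr": fit.hr,
                "ci_low": fit.ci95[0], "ci_high": fit.ci95[1], "p_value": fit.p_value,
            }
        )
    except (ValueError, KeyError):
        pass
    tables["hazard_ratios"] = pd.DataFrame(
        hr_rows, columns=["outcome", "exposure", "n_cases", "hr", "ci_low", "ci_high", "p_value"]
    )

    n = len(records)
    tables["cohort_summary"] = {
        "n_subjects": n,
        "pct_mosaic_carriers": carrier_percent(int(records["exposure_any_mosaic"].sum()), n) if n else np.nan,
        "pct_large_mosaic_carriers": carrier_percent(int(records["exposure_large_mosaic"].sum()), n) if n else np.nan,
    }
    return tables
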
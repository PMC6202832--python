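"""Pipeline stages: tabulation, correlations, suppression ORs, risk factors."""

import json

import numpy as np
import pytest

from cascore import (
    AdherenceClass,
    AdherenceMeasurement,
    ContingencyTable,
    WomanRecord,
    analyze_cohort,
    correlation_matrix,
    odds_ratio,
    risk_factor_analysis,
    suppression_analysis,
    tabulate_adherence,
)
from cascore.cohort_analysis import round_half_up


def make_record(i, measurement, vl=None, in_care_m12=True, reason=None, **covs):
    covariates = {
        "age_group": "25-34",
        "education": "primary",
        "occupation": "informal",
        "cd4_group": ">350",
        "who_stage": "1",
        "religion": "catholic",
    }
    covariates.update(covs)
    return WomanRecord(
        id=f"T{i:03d}",
        covariates=covariates,
        in_care_m6=True,
        in_care_m12=in_care_m12,
        measurement_m6=measurement,
        measurement_m12=measurement if in_care_m12 else None,
        vl_m12=vl if in_care_m12 else None,
        vl_censored=False,
        discontinuation_reason=reason,
    )


PERFECT = AdherenceMeasurement(6, 0, 9.5)  # scores (3,3,3)
MIDDLING = AdherenceMeasurement(5, 1, 8.5)  # scores (2,2,2)
POOR = AdherenceMeasurement(2, 3, 5.0)  # scores (1,1,1)


def test_tabulate_all_high():
    cohort = [make_record(i, PERFECT) for i in range(12)]
    tab = tabulate_adherence(cohort, "m12")
    assert tab.attrs["n_assessed"] == 12
    for instrument in ("refill", "selfreport", "vas", "cas"):
        assert tab.loc[(instrument, "high"), "count"] == 12
        assert tab.loc[(instrument, "high"), "percent"] == 100.0


def test_tabulate_override_lower_bound_and_reconciliation():
    cohort = [make_record(i, PERFECT) for i in range(7)]
    # refill score 1 forces composite low even with perfect self-report/VAS
    cohort += [make_record(100 + i, AdherenceMeasurement(1, 0, 9.9)) for i in range(3)]
    tab = tabulate_adherence(cohort, "m12")
    assert tab.loc[("cas", "low"), "count"] >= 3
    for instrument in ("refill", "selfreport", "vas", "cas"):
        assert tab.loc[instrument]["count"].sum() == 10


def test_correlation_matrix_identical_vectors():
    cohort = [
        make_record(0, PERFECT),
        make_record(1, MIDDLING),
        make_record(2, POOR),
        make_record(3, PERFECT),
    ]
    mat = correlation_matrix(cohort, "m12")
    assert mat.attrs["n"] == 4
    np.testing.assert_allclose(mat.to_numpy(), 1.0)
    np.testing.assert_allclose(mat.to_numpy(), mat.to_numpy().T)


def test_correlation_matrix_flags_constant_vector():
    cohort = [
        make_record(0, AdherenceMeasurement(6, 0, 9.5)),
        make_record(1, AdherenceMeasurement(6, 1, 8.5)),
        make_record(2, AdherenceMeasurement(6, 3, 5.0)),
    ]
    mat = correlation_matrix(cohort, "m12")
    assert np.isnan(mat.loc["refill", "vas"])  # refill constant -> undefined
    assert mat.loc["selfreport", "vas"] == pytest.approx(1.0)


def test_suppression_analysis_worked_example(worked_example):
    tables = suppression_analysis(worked_example)
    cas = tables["cas"]
    assert cas.reference == "moderate"
    assert cas.counts == {"low": (8, 9), "moderate": (4, 34), "high": (0, 110)}
    assert round_half_up(cas.ors["low"].odds_ratio, 1) == 7.6
    assert not cas.ors["high"].defined  # zero failures in the high stratum
    # the driver must agree exactly with the 2x2 estimator it wraps
    direct = odds_ratio(ContingencyTable(8, 9, 4, 34))
    assert cas.ors["low"] == direct
    for inst in ("refill", "selfreport", "vas"):
        assert tables[inst].reference == "high"
        assert tables[inst].n == 165


def test_suppression_all_suppressed_is_undefined():
    cohort = [make_record(i, PERFECT, vl=0.0) for i in range(5)]
    cohort += [make_record(10 + i, POOR, vl=200.0) for i in range(4)]
    tables = suppression_analysis(cohort)
    for tab in tables.values():
        assert all(not r.defined or r.odds_ratio == 1.0 for r in tab.ors.values())


def test_risk_factor_merge_bookkeeping():
    cohort = [make_record(i, PERFECT, vl=0.0) for i in range(20)]
    cohort += [make_record(50 + i, POOR, vl=0.0) for i in range(5)]
    # 6 discontinued: 4 merged as worst-case low, 2 excluded
    cohort += [
        make_record(100 + i, None, in_care_m12=False, reason="ltfu") for i in range(3)
    ]
    cohort += [make_record(110, None, in_care_m12=False, reason="stopped")]
    cohort += [make_record(111, None, in_care_m12=False, reason="transferred")]
    cohort += [make_record(112, None, in_care_m12=False, reason="died")]
    risk = risk_factor_analysis(cohort)
    assert risk.n_population == 25 + 4
    assert risk.n_in_care_m12 == 25
    assert risk.n_discontinued_included == 4
    assert risk.n_excluded == 2
    assert risk.n_low == 5 + 4


def test_risk_factor_no_discontinuations_is_identity():
    cohort = [make_record(i, PERFECT, vl=0.0) for i in range(15)]
    cohort += [make_record(30 + i, POOR, vl=0.0) for i in range(6)]
    risk = risk_factor_analysis(cohort)
    assert risk.n_discontinued_included == 0
    assert risk.n_low == 6


def test_risk_factor_screening_and_forced_covariates(small_cohort):
    risk = risk_factor_analysis(small_cohort)
    for forced in ("age_group", "education", "occupation", "religion", "who_stage", "cd4_group"):
        assert forced in risk.selected
    # every covariate level cross-tab reconciles with the population
    for cov, levels in risk.counts.items():
        assert sum(a + b for a, b in levels.values()) == risk.n_population
    assert risk.fit is not None and risk.fit.converged
    # adjusted ORs exist for every non-reference modelled level
    assert ("education", "primary") in risk.adjusted
    assert ("education", "secondary+") not in risk.adjusted  # reference


def test_analyze_cohort_report(small_cohort):
    report = analyze_cohort(small_cohort)
    ns = report.ns
    assert ns["n_assessed_m6"] >= ns["n_assessed_m12"] >= ns["n_with_vl_m12"]
    assert (
        report.risk.n_population
        == report.risk.n_in_care_m12 + report.risk.n_discontinued_included
    )
    payload = json.loads(report.to_json())
    assert payload["schema_version"] == 1
    assert payload["ns"] == ns
    assert set(payload["suppression"]) == {"refill", "selfreport", "vas", "cas"}
    text = report.to_text()
    assert "Risk factors for low adherence" in text
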
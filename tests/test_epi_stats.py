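"""Odds ratios, Spearman correlation and the IRLS logistic fitter."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from cascore import (
    ContingencyTable,
    categorical_or,
    fit_logistic,
    odds_ratio,
    spearman_rho,
)
from cascore.cohort_analysis import round_half_up


# ---------------------------------------------------------------------------
# 2x2 odds ratios
# ---------------------------------------------------------------------------

def woolf_oracle(a, b, c, d, alpha=0.05):
    """Independent hand computation of the Woolf interval."""
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = sps.norm.ppf(1 - alpha / 2)
    return (
        math.exp(log_or),
        math.exp(log_or - z * se),
        math.exp(log_or + z * se),
    )


@pytest.mark.parametrize(
    "cells, expected_or_1dp",
    [
        ((8, 9, 4, 34), 7.6),     # low vs moderate composite adherence
        ((6, 11, 5, 132), 14.4),  # low vs high pharmacy refill
        ((1, 10, 5, 132), 2.6),   # moderate vs high pharmacy refill
        ((9, 9, 1, 124), 124.0),  # low vs high VAS
        ((2, 20, 1, 124), 12.4),  # moderate vs high VAS
    ],
)
def test_published_crude_ors(cells, expected_or_1dp):
    r = odds_ratio(ContingencyTable(*cells))
    assert r.defined
    assert round_half_up(r.odds_ratio, 1) == expected_or_1dp


def test_woolf_interval_matches_oracle():
    r = odds_ratio(ContingencyTable(6, 11, 5, 132))
    est, lo, hi = woolf_oracle(6, 11, 5, 132)
    assert r.odds_ratio == pytest.approx(est, abs=1e-12)
    assert r.ci_lower == pytest.approx(lo, abs=1e-12)
    assert r.ci_upper == pytest.approx(hi, abs=1e-12)
    assert (round_half_up(r.ci_lower, 1), round_half_up(r.ci_upper, 1)) == (3.8, 54.8)


def test_balanced_table_symmetric_about_one():
    r = odds_ratio(ContingencyTable(1, 1, 1, 1))
    assert r.odds_ratio == pytest.approx(1.0)
    assert r.ci_lower * r.ci_upper == pytest.approx(1.0)  # log-symmetric
    assert r.p_value == pytest.approx(1.0)


def test_zero_cell_is_undefined_unless_haldane():
    r = odds_ratio(ContingencyTable(0, 110, 4, 34))
    assert not r.defined
    assert math.isnan(r.odds_ratio)
    rh = odds_ratio(ContingencyTable(0, 110, 4, 34), haldane=True)
    assert rh.defined
    est, lo, hi = woolf_oracle(0.5, 110.5, 4.5, 34.5)
    assert rh.odds_ratio == pytest.approx(est)


def test_table_validation():
    with pytest.raises(ValueError):
        ContingencyTable(-1, 2, 3, 4)
    with pytest.raises(ValueError):
        ContingencyTable(0, 0, 3, 4)
    with pytest.raises(ValueError):
        odds_ratio(ContingencyTable(1, 2, 3, 4), alpha=1.5)


@settings(max_examples=200, derandomize=True)
@given(st.tuples(*[st.integers(min_value=1, max_value=500)] * 4))
def test_or_properties(cells):
    """Exposure-swap reciprocity, CI covering the estimate, and CI
    narrowing when every cell is scaled up."""
    a, b, c, d = cells
    r = odds_ratio(ContingencyTable(a, b, c, d))
    swapped = odds_ratio(ContingencyTable(c, d, a, b))
    assert r.odds_ratio * swapped.odds_ratio == pytest.approx(1.0)
    assert r.ci_lower < r.odds_ratio < r.ci_upper
    scaled = odds_ratio(ContingencyTable(10 * a, 10 * b, 10 * c, 10 * d))
    assert scaled.odds_ratio == pytest.approx(r.odds_ratio)
    assert (scaled.ci_upper / scaled.ci_lower) < (r.ci_upper / r.ci_lower)


def test_categorical_or_expansion():
    # risk-factor education levels vs completed secondary and above
    education = {
        "none": (1, 4),
        "primary": (59, 75),
        "secondary+": (25, 83),
    }
    out = categorical_or(education, "secondary+")
    assert out["secondary+"].odds_ratio == 1.0
    assert round_half_up(out["primary"].odds_ratio, 1) == 2.6
    assert round_half_up(out["none"].odds_ratio, 1) == 0.8
    age = {"15-24": (29, 40), "25-34": (48, 96), "35+": (8, 26)}
    out = categorical_or(age, "35+")
    assert round_half_up(out["15-24"].odds_ratio, 1) == 2.4
    # two identical rows: no association
    out = categorical_or({"x": (5, 10), "ref": (5, 10)}, "ref")
    assert out["x"].odds_ratio == pytest.approx(1.0)
    with pytest.raises(ValueError):
        categorical_or(education, "postgraduate")


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

def test_spearman_simple_cases():
    assert spearman_rho([1, 2, 3], [1, 2, 3]).rho == pytest.approx(1.0)
    assert spearman_rho([1, 2, 3], [3, 2, 1]).rho == pytest.approx(-1.0)
    with pytest.raises(ValueError):
        spearman_rho([1, 1, 1], [1, 2, 3])
    with pytest.raises(ValueError):
        spearman_rho([1, 2], [1, 2])


def test_spearman_matches_scipy_on_tied_data():
    rng = np.random.default_rng(7)
    for _ in range(50):
        x = rng.integers(1, 4, size=30)
        y = rng.integers(1, 4, size=30)
        if len(set(x)) == 1 or len(set(y)) == 1:
            continue
        ours = spearman_rho(x, y).rho
        ref = sps.spearmanr(x, y).statistic
        assert ours == pytest.approx(ref, abs=1e-12)


@settings(max_examples=100, derandomize=True)
@given(
    st.lists(st.integers(min_value=0, max_value=9), min_size=4, max_size=40).filter(
        lambda v: len(set(v)) > 1
    ),
    st.lists(st.integers(min_value=0, max_value=9), min_size=4, max_size=40).filter(
        lambda v: len(set(v)) > 1
    ),
)
def test_spearman_monotone_transform_invariance(x, y):
    n = min(len(x), len(y))
    x, y = x[:n], y[:n]
    if len(set(x)) == 1 or len(set(y)) == 1:
        return
    base = spearman_rho(x, y).rho
    fx = [math.exp(v) + v**3 for v in x]  # strictly increasing transform
    assert spearman_rho(fx, y).rho == pytest.approx(base, abs=1e-12)


# ---------------------------------------------------------------------------
# Logistic regression
# ---------------------------------------------------------------------------

def saturated_design(a, b, c, d):
    """Single binary predictor encoding a 2x2 table."""
    X = np.column_stack(
        [np.ones(a + b + c + d), np.r_[np.ones(a + b), np.zeros(c + d)]]
    )
    y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
    return X, y


def test_logistic_slope_equals_log_cross_product():
    X, y = saturated_design(8, 9, 4, 34)
    fit = fit_logistic(X, y)
    assert fit.converged
    assert fit.coefficients[1] == pytest.approx(math.log(8 * 34 / (9 * 4)), abs=1e-6)
    assert fit.adjusted_odds_ratios[1] == pytest.approx(8 * 34 / (9 * 4), rel=1e-6)
    # Woolf SE on the log OR is the saturated-model SE
    assert fit.standard_errors[1] == pytest.approx(
        math.sqrt(1 / 8 + 1 / 9 + 1 / 4 + 1 / 34), abs=1e-6
    )


def test_logistic_matches_statsmodels():
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(11)
    n = 300
    X = np.column_stack([np.ones(n), rng.normal(size=(n, 2)), rng.integers(0, 2, n)])
    beta = np.array([-0.5, 0.8, -0.4, 0.6])
    y = (rng.random(n) < 1 / (1 + np.exp(-X @ beta))).astype(float)
    ours = fit_logistic(X, y)
    ref = sm.Logit(y, X).fit(disp=0)
    np.testing.assert_allclose(ours.coefficients, ref.params, atol=1e-6)
    np.testing.assert_allclose(ours.standard_errors, ref.bse, atol=1e-6)


def test_logistic_degenerate_inputs():
    X, y = saturated_design(0, 10, 0, 10)  # all-zero outcome
    fit = fit_logistic(X, y)
    assert not fit.converged
    assert fit.diagnosis == "complete_separation"

    # perfectly separating predictor
    X = np.column_stack([np.ones(20), np.r_[np.zeros(10), np.ones(10)]])
    y = np.r_[np.zeros(10), np.ones(10)]
    fit = fit_logistic(X, y)
    assert not fit.converged
    assert fit.diagnosis == "complete_separation"

    # duplicated column
    X = np.column_stack([np.ones(20), np.arange(20.0), np.arange(20.0)])
    y = np.r_[np.zeros(10), np.ones(10)]
    fit = fit_logistic(X, y)
    assert not fit.converged
    assert fit.diagnosis == "rank_deficient_design"

    with pytest.raises(ValueError):
        fit_logistic(np.ones((5, 1)), np.array([0, 1, 2, 0, 1.0]))
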
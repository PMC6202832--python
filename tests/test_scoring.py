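"""Scoring rules: instrument scores, composite sum, class and override."""

import itertools

import pytest

from cascore import (
    AdherenceClass,
    AdherenceMeasurement,
    CASCutpoints,
    ComponentScores,
    compute_cas,
    score_measurement,
    score_refill,
    score_selfreport,
    score_vas,
)


@pytest.mark.parametrize(
    "refills, expected",
    [(6, 3), (5, 2), (4, 1), (3, 1), (2, 1), (1, 1), (0, 1)],
)
def test_refill_score(refills, expected):
    assert score_refill(refills) == expected


@pytest.mark.parametrize(
    "yes_count, expected",
    [(0, 3), (1, 2), (2, 1), (3, 1), (4, 1)],
)
def test_selfreport_score(yes_count, expected):
    assert score_selfreport(yes_count) == expected


@pytest.mark.parametrize(
    "vas, expected",
    [
        (10.0, 3),
        (9.0, 3),  # boundary: exactly 90% is high
        (8.99, 2),
        (8.0, 2),  # boundary: exactly 80% is moderate
        (7.9, 1),
        (0.0, 1),
    ],
)
def test_vas_score_tenpoint_scale(vas, expected):
    assert score_vas(vas) == expected


@pytest.mark.parametrize("percent, expected", [(95.0, 3), (90.0, 3), (85.0, 2), (79.9, 1)])
def test_vas_score_percent_scale(percent, expected):
    assert score_vas(percent, percent_scale=True) == expected


@pytest.mark.parametrize(
    "func, bad",
    [
        (score_refill, 7),
        (score_refill, -1),
        (score_refill, 5.5),
        (score_selfreport, 5),
        (score_selfreport, -1),
        (score_vas, 10.5),
        (score_vas, -0.1),
    ],
)
def test_out_of_range_inputs_rejected(func, bad):
    with pytest.raises(ValueError):
        func(bad)


def test_measurement_validates_fields():
    with pytest.raises(ValueError, match="refills_collected"):
        AdherenceMeasurement(7, 0, 9.0)
    with pytest.raises(ValueError, match="selfreport_yes"):
        AdherenceMeasurement(6, 5, 9.0)
    with pytest.raises(ValueError, match="vas_value"):
        AdherenceMeasurement(6, 0, 11.0)


@pytest.mark.parametrize(
    "triple, expected_sum, expected_class, expected_override",
    [
        ((3, 3, 3), 9, AdherenceClass.HIGH, False),
        ((2, 2, 2), 6, AdherenceClass.MODERATE, False),
        ((1, 3, 3), 7, AdherenceClass.LOW, True),
        ((1, 1, 1), 3, AdherenceClass.LOW, False),
        ((3, 3, 2), 8, AdherenceClass.HIGH, False),
        ((2, 2, 1), 5, AdherenceClass.MODERATE, False),
        ((2, 1, 1), 4, AdherenceClass.LOW, False),
        ((3, 3, 1), 7, AdherenceClass.MODERATE, False),
    ],
)
def test_composite_examples(triple, expected_sum, expected_class, expected_override):
    result = compute_cas(ComponentScores(*triple))
    assert result.cas_sum == expected_sum
    assert result.adherence_class is expected_class
    assert result.refill_override_applied is expected_override


CLASS_RANK = {AdherenceClass.LOW: 0, AdherenceClass.MODERATE: 1, AdherenceClass.HIGH: 2}


def test_composite_truth_table_exhaustive():
    """All 27 score triples: sum bounds, override totality, monotonicity."""
    results = {}
    for triple in itertools.product((1, 2, 3), repeat=3):
        r = compute_cas(ComponentScores(*triple))
        results[triple] = r
        assert r.cas_sum == sum(triple)
        assert 3 <= r.cas_sum <= 9
        if triple[0] == 1:
            assert r.adherence_class is AdherenceClass.LOW
        # purity: identical input gives identical output
        assert compute_cas(ComponentScores(*triple)) == r
    # monotone non-decreasing in each component when the override is not in play
    for triple, r in results.items():
        for axis in range(3):
            if triple[axis] == 3:
                continue
            bumped = list(triple)
            bumped[axis] += 1
            r2 = results[tuple(bumped)]
            if not (r.refill_override_applied or r2.refill_override_applied):
                assert CLASS_RANK[r2.adherence_class] >= CLASS_RANK[r.adherence_class]


def test_alternative_cutpoints_change_classification():
    strict = CASCutpoints(high_min=9, moderate_min=6)
    assert compute_cas(ComponentScores(3, 3, 2), strict).adherence_class is AdherenceClass.MODERATE
    assert compute_cas(ComponentScores(2, 2, 1), strict).adherence_class is AdherenceClass.LOW
    with pytest.raises(ValueError):
        CASCutpoints(high_min=5, moderate_min=5)


def test_score_measurement_end_to_end():
    comp, cas = score_measurement(AdherenceMeasurement(6, 0, 9.5))
    assert comp.astuple() == (3, 3, 3)
    assert cas.adherence_class is AdherenceClass.HIGH
    comp, cas = score_measurement(AdherenceMeasurement(2, 0, 9.8))
    assert comp.astuple() == (1, 3, 3)
    assert cas.adherence_class is AdherenceClass.LOW
    assert cas.refill_override_applied
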
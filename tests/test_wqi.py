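"""Weighted arithmetic WQI: ratings, unit weights, aggregation, grading."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from aquaindex import (
    InputError,
    MissingDataError,
    ParameterSpec,
    StandardsTable,
    Status,
    WaterSample,
    classify_wqi,
    compute_wqi,
    quality_rating,
    unit_weights,
    ward_wqi,
)

# ---------------------------------------------------------------- unit weights


def test_unit_weights_hand_case(two_param_table):
    wv = unit_weights(two_param_table)
    # k = 1/(1/100 + 1/200) = 200/3; w_A = k/100 = 2/3, w_B = k/200 = 1/3
    assert wv.k == pytest.approx(200.0 / 3.0, abs=1e-12)
    assert wv.weights["A"] == pytest.approx(2.0 / 3.0, abs=1e-12)
    assert wv.weights["B"] == pytest.approx(1.0 / 3.0, abs=1e-12)


def test_unit_weights_single_parameter():
    table = StandardsTable([ParameterSpec("A", "mg/l", 0.0, 45.0, 45.0)])
    wv = unit_weights(table)
    assert wv.weights == {"A": 1.0}
    assert wv.k == pytest.approx(45.0)


@given(
    st.lists(st.floats(min_value=0.1, max_value=1e4), min_size=1, max_size=12,
             unique=True)
)
def test_unit_weights_sum_to_one_for_arbitrary_tables(standards_values):
    table = StandardsTable(
        ParameterSpec(f"p{i}", "mg/l", 0.0, s, s)
        for i, s in enumerate(standards_values)
    )
    wv = unit_weights(table)
    assert abs(sum(wv.weights.values()) - 1.0) <= 1e-12
    assert all(w > 0 for w in wv.weights.values())


def test_unit_weights_unknown_parameter(standards):
    from aquaindex import UnknownParameterError

    with pytest.raises(UnknownParameterError):
        unit_weights(standards, subset=["ph", "lead"])


# -------------------------------------------------------------- quality rating


def test_rating_zero_at_ideal(standards):
    assert quality_rating(7.0, standards["ph"]) == 0.0
    assert quality_rating(14.6, standards["dissolved_oxygen"]) == 0.0


def test_rating_hundred_at_standard(standards):
    for spec in standards:
        assert quality_rating(spec.standard_value, spec) == 100.0


def test_rating_nitrate_midpoint(standards):
    assert quality_rating(22.5, standards["nitrate"]) == 50.0


def test_rating_signed_vs_absolute(standards):
    # acidic pH lies on the far side of the ideal from the standard
    ph = standards["ph"]
    assert quality_rating(5.5, ph, mode="signed") == pytest.approx(-100.0)
    assert quality_rating(5.5, ph, mode="absolute") == pytest.approx(100.0)


def test_rating_is_affine_in_value(standards):
    spec = standards["hardness"]
    q = lambda v: quality_rating(v, spec)
    # constant finite-difference slope at three widely spaced points
    s1 = (q(50.0) - q(0.0)) / 50.0
    s2 = (q(400.0) - q(100.0)) / 300.0
    assert s1 == pytest.approx(s2, abs=1e-12)


# ----------------------------------------------------------------- compute_wqi


def test_wqi_exact_anchors(standards):
    at_standard = {s.name: s.standard_value for s in standards}
    at_ideal = {s.name: s.ideal_value for s in standards}
    assert compute_wqi(at_standard, standards).score == 100.0
    assert compute_wqi(at_ideal, standards).score == 0.0


def test_wqi_two_parameter_hand_case(two_param_table):
    # q_A = 50, q_B = 100; w = (2/3, 1/3) -> 50*2/3 + 100/3 = 200/3
    res = compute_wqi({"A": 50.0, "B": 200.0}, two_param_table)
    assert res.score == pytest.approx(200.0 / 3.0, abs=1e-9)
    assert res.status is Status.POOR


def test_wqi_result_recomputable(standards):
    values = {s.name: 0.5 * (s.ideal_value + s.standard_value) for s in standards}
    res = compute_wqi(values, standards)
    assert res.recompute_score() == pytest.approx(res.score, abs=1e-9)


def test_wqi_strict_missing_names_parameter(standards):
    values = {s.name: s.standard_value for s in standards if s.name != "nitrate"}
    with pytest.raises(MissingDataError, match="nitrate"):
        compute_wqi(values, standards, missing_policy="strict")


def test_wqi_renormalize_single_parameter_equals_rating(standards):
    res = compute_wqi({"nitrate": 22.5}, standards, missing_policy="renormalize")
    assert res.score == pytest.approx(50.0, abs=1e-12)


def test_wqi_empty_values_rejected(standards):
    with pytest.raises(InputError):
        compute_wqi({}, standards)


def test_wqi_affine_in_each_parameter(standards):
    base = {s.name: 0.5 * (s.ideal_value + s.standard_value) for s in standards}
    for name in ("hardness", "ph", "dissolved_oxygen"):
        lo, hi = dict(base), dict(base)
        lo[name] = base[name] - 0.5
        hi[name] = base[name] + 0.5
        mid = compute_wqi(base, standards).score
        assert 0.5 * (compute_wqi(lo, standards).score
                      + compute_wqi(hi, standards).score) == pytest.approx(mid, abs=1e-9)


@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_wqi_matches_naive_oracle(seed):
    """Composed implementation agrees with a naive direct evaluation of the
    three formulas on random 10-parameter inputs."""
    import numpy as np

    from aquaindex import builtin_is10500

    rng = np.random.default_rng(seed)
    standards = builtin_is10500()
    values = {
        s.name: float(rng.uniform(0.1, 13.9)) if s.name == "ph"
        else float(rng.uniform(0.0, 1.5 * s.standard_value))
        for s in standards
    }
    # independent oracle: literal formulas, composed naively
    inv_sum = sum(1.0 / s.standard_value for s in standards)
    k = 1.0 / inv_sum
    num = den = 0.0
    for s in standards:
        w = k / s.standard_value
        q = 100.0 * (values[s.name] - s.ideal_value) / (s.standard_value - s.ideal_value)
        num += q * w
        den += w
    assert compute_wqi(values, standards).score == pytest.approx(num / den, abs=1e-9)


# ---------------------------------------------------------------- classify_wqi


@pytest.mark.parametrize(
    ("score", "status"),
    [
        (0.0, Status.EXCELLENT),
        (23.0, Status.EXCELLENT),
        (25.0, Status.EXCELLENT),
        (25.0001, Status.GOOD),
        (50.0, Status.GOOD),
        (51.0, Status.POOR),
        (75.0, Status.POOR),
        (100.0, Status.VERY_POOR),
        (100.0001, Status.UNSUITABLE),
        (101.0, Status.UNSUITABLE),
    ],
)
def test_grade_bands(score, status):
    assert classify_wqi(score) is status


def test_negative_score_grades_excellent_with_warning(caplog):
    import logging

    with caplog.at_level(logging.WARNING, logger="aquaindex.wqi"):
        assert classify_wqi(-5.0) is Status.EXCELLENT
    assert any("negative" in r.message for r in caplog.records)


def test_nonfinite_score_rejected():
    with pytest.raises(InputError):
        classify_wqi(math.nan)


# -------------------------------------------------------------------- ward_wqi


def _sample(sid, ward, values):
    return WaterSample(sample_id=sid, ward=ward, zone="north", values=values)


def test_ward_of_one_sample_equals_sample_wqi(standards):
    values = {s.name: 0.5 * (s.ideal_value + s.standard_value) for s in standards}
    [res] = ward_wqi([_sample("s1", "w1", values)], standards)
    assert res.entity_id == "w1"
    assert res.score == pytest.approx(compute_wqi(values, standards).score, abs=1e-12)


def test_ward_mean_is_idempotent_for_identical_samples(standards):
    values = {s.name: 0.7 * s.standard_value + 0.3 * s.ideal_value for s in standards}
    one = ward_wqi([_sample("a", "w", values)], standards)[0].score
    two = ward_wqi([_sample("a", "w", values), _sample("b", "w", dict(values))],
                   standards)[0].score
    assert two == pytest.approx(one, abs=1e-12)


def test_ward_mean_of_ideal_and_standard_scores_fifty():
    table = StandardsTable([ParameterSpec("A", "mg/l", 0.0, 100.0, 100.0)])
    samples = [_sample("a", "w", {"A": 0.0}), _sample("b", "w", {"A": 100.0})]
    [res] = ward_wqi(samples, table)
    assert res.score == pytest.approx(50.0, abs=1e-12)


def test_ward_wqi_one_result_per_ward(standards):
    values = {s.name: s.standard_value for s in standards}
    samples = [_sample(f"s{i}", f"w{i % 3}", dict(values)) for i in range(9)]
    results = ward_wqi(samples, standards)
    assert sorted(r.entity_id for r in results) == ["w0", "w1", "w2"]
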
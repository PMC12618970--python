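"""Exceedance flags, group summaries, and WQI status distributions."""

import math
import random

import pytest

from aquaindex import (
    InputError,
    Status,
    WaterSample,
    builtin_is10500,
    compute_wqi,
    exceeds_limit,
    status_distribution,
    summarize,
)
from aquaindex.summary import distributions_to_frame, summaries_to_frame

# --------------------------------------------------------------- exceeds_limit


@pytest.mark.parametrize(
    ("parameter", "value", "expected"),
    [
        ("ph", 5.56, True),        # acidic deviation below the 6.5-8.5 band
        ("ph", 8.61, True),
        ("ph", 7.2, False),
        ("ph", 8.5, False),        # exactly at the bound passes
        ("ph", 6.5, False),
        ("dissolved_oxygen", 5.91, True),   # low DO deviates from 6.5-8
        ("dissolved_oxygen", 8.2, True),
        ("dissolved_oxygen", 7.5, False),
        ("nitrate", 30.0, False),  # the study's maximum stayed within 45
        ("nitrate", 45.0, False),
        ("nitrate", 45.1, True),
        ("conductivity", 300.0, False),
        ("conductivity", 300.5, True),
        ("bod", 5.0, False),       # "<5.0" treated as inclusive-pass bound
        ("bod", 5.01, True),
    ],
)
def test_exceeds_limit(standards, parameter, value, expected):
    assert exceeds_limit(value, standards[parameter]) is expected


def test_exceeds_limit_nonfinite_rejected(standards):
    with pytest.raises(InputError):
        exceeds_limit(math.nan, standards["ph"])


# ------------------------------------------------------------------- summarize


def _mk(sid, zone, values, ward="w1"):
    return WaterSample(sample_id=sid, ward=ward, zone=zone, values=values)


def test_summarize_hand_statistics(standards):
    samples = [_mk(f"s{i}", "north", {"hardness": v}) for i, v in enumerate([1.0, 2.0, 3.0])]
    [row] = [r for r in summarize(samples, standards) if not r.empty]
    assert (row.n, row.minimum, row.maximum) == (3, 1.0, 3.0)
    assert row.mean == pytest.approx(2.0)
    assert row.sd == pytest.approx(1.0)  # sample SD, n-1 denominator
    assert row.n_exceed == 0 and row.pct_exceed == 0.0


def test_summarize_southeast_conductivity_percentage(standards):
    """125 samples with 90 over the 300 uS/cm limit -> 72.00% exceedance."""
    values = [400.0] * 90 + [200.0] * 35
    samples = [_mk(f"s{i}", "south_east", {"conductivity": v})
               for i, v in enumerate(values)]
    row = next(r for r in summarize(samples, standards)
               if r.parameter == "conductivity")
    assert row.n == 125
    assert row.n_exceed == 90
    assert row.pct_exceed == 72.00
    assert row.pct_exceed_raw == pytest.approx(100.0 * 90 / 125)


def test_summarize_is_permutation_invariant(standards):
    rng = random.Random(7)
    samples = [
        _mk(f"s{i}", rng.choice(["north", "south_east"]),
            {"hardness": rng.uniform(10, 300), "ph": rng.uniform(5, 9)})
        for i in range(40)
    ]
    shuffled = samples[:]
    rng.shuffle(shuffled)
    a = summaries_to_frame(summarize(samples, standards))
    b = summaries_to_frame(summarize(shuffled, standards))
    # same rows regardless of input order (group order may differ)
    key = ["zone", "parameter"]
    a = a.sort_values(key).reset_index(drop=True)
    b = b.sort_values(key).reset_index(drop=True)
    assert a.equals(b)


def test_summarize_empty_parameter_flagged_not_raised(standards):
    samples = [_mk("s1", "north", {"ph": 7.0})]
    rows = summarize(samples, standards)
    assert len(rows) == 10  # one per standards parameter
    nitrate = next(r for r in rows if r.parameter == "nitrate")
    assert nitrate.empty and nitrate.n == 0
    assert math.isnan(nitrate.mean)


def test_summarize_recomputable_percentage(standards):
    samples = [_mk(f"s{i}", "north", {"hardness": v})
               for i, v in enumerate([100.0, 250.0, 150.0, 300.0])]
    row = next(r for r in summarize(samples, standards) if r.parameter == "hardness")
    assert row.pct_exceed_raw == pytest.approx(100.0 * row.n_exceed / row.n)


def test_summarize_by_ward(standards):
    samples = [
        _mk("a", "north", {"ph": 7.0}, ward="w1"),
        _mk("b", "north", {"ph": 9.0}, ward="w2"),
    ]
    rows = [r for r in summarize(samples, standards, group_key="ward") if not r.empty]
    assert {r.zone for r in rows} == {"w1", "w2"}


# ---------------------------------------------------------- status_distribution


def _results_with_bands(n_excellent, n_good, zone_label="north"):
    """WQI results computed from single-parameter inputs landing in the
    requested bands (f*standard scores 100f for an ideal-0 parameter)."""
    standards = builtin_is10500()
    results, zone_of = [], {}
    fractions = [0.20] * n_excellent + [0.40] * n_good
    for i, f in enumerate(fractions):
        values = {s.name: s.ideal_value + f * (s.standard_value - s.ideal_value)
                  for s in standards}
        r = compute_wqi(values, standards, entity_id=f"ward_{i}")
        results.append(r)
        zone_of[r.entity_id] = zone_label
    return results, zone_of


def test_north_zone_distribution_five_excellent_sixteen_good():
    """21 wards, 5 excellent + 16 good -> 23.81% / 76.19%."""
    results, zone_of = _results_with_bands(5, 16)
    assert [r.status for r in results].count(Status.EXCELLENT) == 5
    [dist] = status_distribution(results, zone_of)
    assert dist.percentages[Status.EXCELLENT] == 23.81
    assert dist.percentages[Status.GOOD] == 76.19
    assert dist.percentages[Status.POOR] == 0.0


def test_distribution_all_same_status():
    results, zone_of = _results_with_bands(4, 0)
    [dist] = status_distribution(results, zone_of)
    assert dist.percentages[Status.EXCELLENT] == 100.0


def test_distribution_uniform_split():
    standards = builtin_is10500()
    fractions = [0.2, 0.4, 0.6, 0.9]  # one entity per band except unsuitable
    results = []
    for i, f in enumerate(fractions):
        values = {s.name: s.ideal_value + f * (s.standard_value - s.ideal_value)
                  for s in standards}
        results.append(compute_wqi(values, standards, entity_id=f"e{i}"))
    [dist] = status_distribution(results, {f"e{i}": "z" for i in range(4)})
    assert [dist.percentages[s] for s in
            (Status.EXCELLENT, Status.GOOD, Status.POOR, Status.VERY_POOR)] == [25.0] * 4


def test_distribution_percentages_sum_to_100():
    results, zone_of = _results_with_bands(5, 16)
    [dist] = status_distribution(results, zone_of)
    assert sum(dist.percentages.values()) == pytest.approx(100.0, abs=0.05)
    frame = distributions_to_frame([dist])
    assert len(frame) == 5  # every band reported, absent ones as zero


def test_distribution_unmapped_entity_is_error():
    from aquaindex import UnknownParameterError

    results, _ = _results_with_bands(1, 1)
    with pytest.raises(UnknownParameterError):
        status_distribution(results, {})
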
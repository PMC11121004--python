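"""The modified PDC metric: arithmetic, carryover, classification, properties."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rxadhere.pdc import (
    DEFAULT_CAP_DAYS,
    GROUP_80_TO_90,
    GROUP_ABOVE_90,
    GROUP_BELOW_80,
    InsufficientFills,
    adherence_summary,
    build_fills,
    classify_adherence,
    compute_adherence,
    compute_overall_doac_pdc,
    compute_pdc,
    days_supply,
)
from rxadhere.records import DEFAULT_REGIMENS
from rxadhere.synth import truth_overall_pdc, truth_pdc


@pytest.mark.parametrize(
    "quantity, substance, expected",
    [
        (60, "dabigatran", 30),   # 2/day
        (30, "rivaroxaban", 30),  # 1/day
        (56, "apixaban", 28),     # 2/day
        (200, "rivaroxaban", 90),  # capped at the 3-month course limit
        (181, "dabigatran", 90),
    ],
)
def test_days_supply(quantity, substance, expected):
    assert days_supply(quantity, DEFAULT_REGIMENS[substance]) == expected


def test_days_supply_subday_errors():
    with pytest.raises(ValueError, match="sub-day"):
        days_supply(1, DEFAULT_REGIMENS["apixaban"])
    with pytest.raises(ValueError):
        days_supply(0, DEFAULT_REGIMENS["rivaroxaban"])


@pytest.mark.parametrize(
    "fills, expected",
    [
        ([(0, 30), (30, 30)], 100.0),            # gapless refill
        ([(0, 30), (40, 30), (80, 30)], 75.0),   # (30 + 30) / 80
        ([(0, 30), (20, 30), (60, 30)], 100.0),  # carryover bridges to day 60
        ([(0, 10), (50, 10)], 20.0),
        ([(0, 90), (100, 90)], 90.0),
    ],
)
def test_compute_pdc_examples(fills, expected):
    assert compute_pdc(fills) == pytest.approx(expected)


def test_compute_pdc_requires_two_fills():
    with pytest.raises(InsufficientFills):
        compute_pdc([(0, 30)])
    # same-day fills merge into one event
    with pytest.raises(InsufficientFills):
        compute_pdc([(5, 30), (5, 30)])


def test_compute_pdc_accepts_calendar_dates():
    fills = [(pd.Timestamp("2019-01-01"), 30), (pd.Timestamp("2019-01-31"), 30)]
    assert compute_pdc(fills) == pytest.approx(100.0)


def test_denominator_mode_drop_last():
    fills = [(0, 30), (40, 30), (80, 30)]
    # dropping the last fill: window [0, 40), covered 30 -> 75%
    assert compute_pdc(fills, denominator_mode="drop_last") == pytest.approx(75.0)
    with pytest.raises(InsufficientFills):
        compute_pdc([(0, 30), (40, 30)], denominator_mode="drop_last")


def test_carryover_off_never_exceeds_on():
    fills = [(0, 30), (10, 30), (70, 30)]
    on = compute_pdc(fills, carryover=True)
    off = compute_pdc(fills, carryover=False)
    assert off <= on
    assert off == pytest.approx(100.0 * 40 / 70)


@pytest.mark.parametrize(
    "pdc, group",
    [
        (75, GROUP_BELOW_80), (79.99, GROUP_BELOW_80), (80, GROUP_80_TO_90),
        (85, GROUP_80_TO_90), (90, GROUP_80_TO_90), (90.01, GROUP_ABOVE_90),
        (100, GROUP_ABOVE_90), (0, GROUP_BELOW_80),
    ],
)
def test_classify_adherence_boundaries(pdc, group):
    assert classify_adherence(pdc) == group


def test_classify_adherence_rejects_out_of_range():
    for bad in (-1, 100.5, float("nan")):
        with pytest.raises(ValueError):
            classify_adherence(bad)


def _records(rows):
    return pd.DataFrame(rows)


def _fill_row(pid, date, substance, quantity):
    return {
        "patient_id": pid, "dispense_date": pd.Timestamp(date),
        "dispensed_substance": substance, "quantity": quantity,
    }


def test_build_fills_merges_same_day_and_recaps():
    rec = _records(
        [
            _fill_row("P1", "2019-01-01", "rivaroxaban", 30),
            _fill_row("P1", "2019-01-01", "rivaroxaban", 30),
            _fill_row("P2", "2019-01-01", "rivaroxaban", 90),
            _fill_row("P2", "2019-01-01", "rivaroxaban", 90),
        ]
    )
    fills = build_fills(rec)
    assert fills.loc[fills.patient_id == "P1", "days_supply"].tolist() == [60]
    # merged supply is re-capped at 90
    assert fills.loc[fills.patient_id == "P2", "days_supply"].tolist() == [90]


def test_build_fills_excludes_non_doacs():
    rec = _records(
        [
            _fill_row("P1", "2019-01-01", "warfarin", 30),
            _fill_row("P1", "2019-02-01", "amiodarone", 30),
        ]
    )
    assert len(build_fills(rec)) == 0
    assert len(build_fills(rec.iloc[:0])) == 0


def test_overall_union_coverage_across_switch():
    fills = {
        "rivaroxaban": [(0, 30)],
        "dabigatran": [(30, 30)],
        "edoxaban": [(60, 30)],
    }
    assert compute_overall_doac_pdc(fills) == pytest.approx(100.0)


def test_overall_single_agent_reduces_to_compute_pdc():
    fills = [(0, 30), (45, 30), (100, 15)]
    assert compute_overall_doac_pdc({"rivaroxaban": fills}) == compute_pdc(fills)


def test_overall_union_at_least_each_agent():
    by_agent = {
        "rivaroxaban": [(0, 10), (50, 10), (120, 10)],
        "apixaban": [(30, 10), (90, 10), (110, 10)],
    }
    union = compute_overall_doac_pdc(by_agent)
    lo = min(d for fl in by_agent.values() for d, _ in fl)
    hi = max(d for fl in by_agent.values() for d, _ in fl)
    for fills in by_agent.values():
        segs = []
        t = None
        for d, s in fills:
            start = d if t is None or t < d else t
            segs.append((start, start + s))
            t = start + s
        covered = sum(min(b, hi) - max(a, lo) for a, b in segs
                      if min(b, hi) > max(a, lo))
        assert union >= 100.0 * covered / (hi - lo) - 1e-9


def test_adherence_summary_hand_computed():
    res = pd.DataFrame(
        [
            {"patient_id": "P1", "scope": "overall_doac", "agent": None,
             "pdc": 100.0, "group": GROUP_ABOVE_90, "excluded": False},
            {"patient_id": "P2", "scope": "overall_doac", "agent": None,
             "pdc": 85.0, "group": GROUP_80_TO_90, "excluded": False},
            {"patient_id": "P3", "scope": "overall_doac", "agent": None,
             "pdc": 50.0, "group": GROUP_BELOW_80, "excluded": False},
        ]
    )
    s = adherence_summary(res)
    assert s["mean_pdc"] == pytest.approx(78.3333, abs=1e-3)
    assert s["share_at_or_above_80_pct"] == pytest.approx(66.667, abs=1e-2)
    assert s["group_counts"] == {GROUP_BELOW_80: 1, GROUP_80_TO_90: 1,
                                 GROUP_ABOVE_90: 1}
    assert sum(s["group_counts"].values()) == s["n_scored"]


def test_compute_adherence_matches_ground_truth(cohort_small):
    records, truth = cohort_small
    res = compute_adherence(records)
    overall = (
        res[(res.scope == "overall_doac") & (~res.excluded)]
        .set_index("patient_id")["pdc"]
        .sort_index()
    )
    expected = (
        truth.patients.set_index("patient_id")["true_overall_pdc"]
        .dropna()
        .sort_index()
    )
    assert len(overall) == len(expected)
    assert (overall.to_numpy() == expected.to_numpy()).all()


# ---------------------------------------------------------------- properties

fill_lists = st.lists(
    st.tuples(st.integers(0, 400), st.integers(1, DEFAULT_CAP_DAYS)),
    min_size=2, max_size=12,
).filter(lambda fl: len({d for d, _ in fl}) >= 2)


@settings(derandomize=True, max_examples=300, deadline=None)
@given(fill_lists)
def test_pdc_equals_day_by_day_oracle(fills):
    assert compute_pdc(fills) == truth_pdc(fills)


@settings(derandomize=True, max_examples=200, deadline=None)
@given(fill_lists, st.integers(-1000, 1000))
def test_pdc_translation_invariance(fills, shift):
    shifted = [(d + shift, s) for d, s in fills]
    assert compute_pdc(shifted) == compute_pdc(fills)


@settings(derandomize=True, max_examples=200, deadline=None)
@given(fill_lists)
def test_pdc_range_and_full_coverage(fills):
    pdc = compute_pdc(fills)
    assert 0.0 <= pdc <= 100.0
    days = sorted({d for d, _ in fills})
    if pdc == 100.0:
        # every day in [first, last) must be covered by the oracle too
        assert truth_pdc(fills) == 100.0


@settings(derandomize=True, max_examples=200, deadline=None)
@given(fill_lists, st.integers(1, 399), st.integers(1, DEFAULT_CAP_DAYS))
def test_pdc_monotone_under_added_fill(fills, frac, supply):
    days = [d for d, _ in fills]
    lo, hi = min(days), max(days)
    if hi - lo < 2:
        return
    inside = lo + 1 + frac % (hi - lo - 1)
    augmented = fills + [(inside, supply)]
    assert compute_pdc(augmented) >= compute_pdc(fills)


@settings(derandomize=True, max_examples=200, deadline=None)
@given(fill_lists)
def test_carryover_dominates_no_carryover(fills):
    assert compute_pdc(fills, carryover=False) <= compute_pdc(fills, carryover=True)


agent_fills = st.dictionaries(
    st.sampled_from(["rivaroxaban", "dabigatran", "edoxaban", "apixaban"]),
    st.lists(
        st.tuples(st.integers(0, 400), st.integers(1, DEFAULT_CAP_DAYS)),
        min_size=1, max_size=6,
    ),
    min_size=1, max_size=4,
).filter(
    lambda d: len({(a, dd) for a, fl in d.items() for dd, _ in fl}) >= 2
    and len({dd for fl in d.values() for dd, _ in fl}) >= 2
)


@settings(derandomize=True, max_examples=300, deadline=None)
@given(agent_fills)
def test_overall_pdc_equals_day_by_day_oracle(by_agent):
    assert compute_overall_doac_pdc(by_agent) == truth_overall_pdc(by_agent)
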
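"""Estimators against hand-countable logs and closed-form constructions."""

import math

import pandas as pd
import pytest

from careflow.errors import ClassificationError, EstimationError
from careflow.estimation import (
    classify_avoidable,
    collect_delay_samples,
    estimate_arrival_rates,
    estimate_avoidable_proportions,
    estimate_disposition_weights,
    estimate_timely_proportions,
    estimate_transitions,
    validate_event_log,
)
from careflow.parameters import ServiceKind

S = ServiceKind


def _row(pid, t, service, code="", inv="", trt="", ref="", t1="", end=""):
    return {
        "patient_id": pid,
        "timestamp": float(t),
        "service": service.value if isinstance(service, S) else service,
        "disposition_code": code,
        "ed_investigations": inv,
        "ed_treatments": trt,
        "ed_referral": ref,
        "is_type1_ed": t1,
        "end_timestamp": end,
    }


def _log(rows):
    return pd.DataFrame(rows)


# --- avoidable classification -------------------------------------------------

def test_type1_ed_with_no_resource_use_is_avoidable():
    row = _row("p1", 10, S.ED, inv="false", trt="false", ref="false", t1="true")
    assert classify_avoidable(row) is True


def test_any_resource_use_disqualifies():
    row = _row("p1", 10, S.ED, inv="false", trt="true", ref="false", t1="true")
    assert classify_avoidable(row) is False


def test_non_type1_ed_is_never_avoidable():
    row = _row("p1", 10, S.ED, inv="false", trt="false", ref="false", t1="false")
    assert classify_avoidable(row) is False


def test_missing_flag_raises_classification_error():
    row = _row("p1", 10, S.ED, inv="false", trt="false", ref="false", t1="")
    with pytest.raises(ClassificationError):
        classify_avoidable(row)


# --- arrival rates ------------------------------------------------------------

def test_two_calls_per_hour_recovers_thirty_minute_means():
    # deterministic: calls at minutes 10 and 40 of every hour for a year
    rows = []
    for day in range(365):
        for hour in range(24):
            base = day * 1440 + hour * 60
            for off in (10.0, 40.0):
                rows.append(_row(f"p{base}_{off}", base + off, S.INDEX_111, code="A"))
    rates = estimate_arrival_rates(_log(rows))
    for stratum, mean in rates.items():
        assert mean == pytest.approx(30.0, rel=0.02), stratum


def test_no_weekend_calls_gives_infinite_weekend_means():
    rows = [
        _row(f"p{d}", d * 1440 + 3 * 1440 + 600, S.INDEX_111, code="A")
        for d in range(0, 300, 7)  # day 3 of each week = Monday (Friday start)
    ]
    rates = estimate_arrival_rates(_log(rows))
    assert all(
        math.isinf(m) for (h, q, wk), m in rates.items() if wk
    )


def test_single_quarter_span_warns_about_uncovered_quarters():
    rows = [_row(f"p{i}", i * 600.0, S.INDEX_111, code="A") for i in range(200)]
    with pytest.warns(UserWarning, match=r"\[2, 3, 4\]"):
        rates = estimate_arrival_rates(_log(rows), span_minutes=90 * 1440.0)
    assert all(math.isinf(m) for (h, q, wk), m in rates.items() if q != 1)


def test_empty_log_raises():
    with pytest.raises(EstimationError):
        estimate_arrival_rates(_log([_row("p1", 5, S.PRIMARY_CARE)]))


# --- transitions --------------------------------------------------------------

def test_transitions_match_hand_tally_of_four_patients():
    # q1 (all timestamps in January), hand-countable:
    #   p1: 111 -> PC -> exit            (gp_first=True)
    #   p2: 111 -> PC -> ED -> exit      (gp_first=True)
    #   p3: 111 -> ED -> exit            (gp_first=False)
    #   p4: 111 -> exit                  (gp_first=False)
    rows = [
        _row("p1", 0, S.INDEX_111, code="A"),
        _row("p1", 100, S.PRIMARY_CARE),
        _row("p2", 1000, S.INDEX_111, code="A"),
        _row("p2", 1100, S.PRIMARY_CARE),
        _row("p2", 1500, S.ED, inv="true", trt="false", ref="false", t1="true"),
        _row("p3", 2000, S.INDEX_111, code="B"),
        _row("p3", 2300, S.ED, inv="false", trt="false", ref="false", t1="true"),
        _row("p4", 3000, S.INDEX_111, code="B"),
    ]
    transitions, _prov = estimate_transitions(_log(rows))
    # INDEX_111 row is the marginal over all 4 patients: PC 2/4, ED 1/4, exit 1/4
    for gp in (False, True):
        row = transitions[(S.INDEX_111, gp, 1)]
        assert row[S.PRIMARY_CARE] == pytest.approx(0.5)
        assert row[S.ED] == pytest.approx(0.25)
        assert row[S.NO_FURTHER_CONTACT] == pytest.approx(0.25)
    # PRIMARY_CARE, gp=True: p1 exits, p2 goes to ED -> 1/2 each
    pc_row = transitions[(S.PRIMARY_CARE, True, 1)]
    assert pc_row[S.ED] == pytest.approx(0.5)
    assert pc_row[S.NO_FURTHER_CONTACT] == pytest.approx(0.5)
    # ED rows: both observed ED visits exit
    assert transitions[(S.ED, True, 1)][S.NO_FURTHER_CONTACT] == pytest.approx(1.0)
    assert transitions[(S.ED, False, 1)][S.NO_FURTHER_CONTACT] == pytest.approx(1.0)


def test_index_only_patient_is_absorbing():
    transitions, _ = estimate_transitions(
        _log([_row("p1", 50.0, S.INDEX_111, code="A")])
    )
    row = transitions[(S.INDEX_111, False, 1)]
    assert row == {S.NO_FURTHER_CONTACT: 1.0}


def test_sparse_rows_fall_back_and_are_flagged():
    transitions, prov = estimate_transitions(
        _log(
            [
                _row("p1", 0, S.INDEX_111, code="A"),
                _row("p1", 100, S.PRIMARY_CARE),
            ]
        )
    )
    # every (source, gp, quarter) row exists and sums to 1
    total_rows = len(transitions)
    assert total_rows == 6 * 2 * 4
    for row in transitions.values():
        assert sum(row.values()) == pytest.approx(1.0)
    assert prov["transition_fallbacks"]  # sparse strata were filled in


# --- weights / timely / avoidable / delays -----------------------------------

def test_disposition_weights_are_index_frequencies():
    rows = [
        _row("p1", 0, S.INDEX_111, code="A"),
        _row("p2", 10, S.INDEX_111, code="A"),
        _row("p3", 20, S.INDEX_111, code="B"),
        _row("p4", 30, S.INDEX_111, code="A"),
    ]
    weights = estimate_disposition_weights(_log(rows))
    assert weights == {"A": pytest.approx(0.75), "B": pytest.approx(0.25)}


@pytest.mark.parametrize("among", ["pc_first", "all"])
def test_first_contact_at_half_timeframe_is_always_timely(among):
    timeframes = {"A": 120.0, "B": 360.0}
    rows = []
    for i, code in enumerate(["A", "A", "B"]):
        t0 = i * 5000.0
        rows.append(_row(f"p{i}", t0, S.INDEX_111, code=code))
        rows.append(_row(f"p{i}", t0 + timeframes[code] / 2, S.PRIMARY_CARE))
    timely = estimate_timely_proportions(_log(rows), timeframes, among=among)
    assert timely == {"A": pytest.approx(1.0), "B": pytest.approx(1.0)}


def test_all_caller_definition_counts_non_attenders_as_not_timely():
    timeframes = {"A": 120.0}
    rows = [
        _row("p1", 0, S.INDEX_111, code="A"),
        _row("p1", 60, S.PRIMARY_CARE),
        _row("p2", 5000, S.INDEX_111, code="A"),  # never reaches primary care
    ]
    assert estimate_timely_proportions(_log(rows), timeframes, among="all")[
        "A"
    ] == pytest.approx(0.5)
    assert estimate_timely_proportions(_log(rows), timeframes, among="pc_first")[
        "A"
    ] == pytest.approx(1.0)


def test_missing_timeframe_is_an_error():
    rows = [_row("p1", 0, S.INDEX_111, code="Z")]
    with pytest.raises(EstimationError, match="Z"):
        estimate_timely_proportions(_log(rows), {"A": 120.0})


def test_avoidable_proportions_pool_and_flag_empty_strata():
    rows = [
        _row("p1", 0, S.INDEX_111, code="A"),
        _row("p1", 100, S.ED, inv="false", trt="false", ref="false", t1="true"),
        _row("p2", 5000, S.INDEX_111, code="A"),
        _row("p2", 5100, S.ED, inv="true", trt="false", ref="false", t1="true"),
    ]
    table, info = estimate_avoidable_proportions(_log(rows))
    # both ED rows have gp_first=False: 1 avoidable of 2
    assert table[("A", False)] == pytest.approx(0.5)
    # empty (A, True) stratum falls back to the code's pooled value
    assert table[("A", True)] == pytest.approx(0.5)
    assert info["pooled_proportion"] == pytest.approx(0.5)
    assert any("gp=True" in f for f in info["avoidable_fallbacks"])


def test_unclassifiable_ed_rows_are_excluded_and_counted():
    rows = [
        _row("p1", 0, S.INDEX_111, code="A"),
        _row("p1", 100, S.ED, inv="false", trt="false", ref="false", t1="true"),
        _row("p2", 5000, S.INDEX_111, code="A"),
        _row("p2", 5100, S.ED),  # flags missing entirely
    ]
    _table, info = estimate_avoidable_proportions(_log(rows))
    assert info["n_classified"] == 1
    assert info["n_unclassifiable"] == 1


def test_delay_samples_use_end_timestamps_where_present():
    rows = [
        _row("p1", 0, S.INDEX_111, code="A", end=10.0),
        _row("p1", 100, S.PRIMARY_CARE, end=115.0),
        _row("p1", 400, S.ED, inv="true", trt="false", ref="false", t1="true", end=460.0),
    ]
    queue, activity = collect_delay_samples(_log(rows))
    assert queue[(S.INDEX_111, S.PRIMARY_CARE)] == [pytest.approx(90.0)]  # 100 - 10
    assert queue[(S.PRIMARY_CARE, S.ED)] == [pytest.approx(285.0)]  # 400 - 115
    assert activity[S.PRIMARY_CARE] == [pytest.approx(15.0)]
    assert activity[S.ED] == [pytest.approx(60.0)]


def test_event_log_validation_catches_structural_breaks():
    rows = [
        _row("p1", 0, S.INDEX_111, code="A"),
        _row("p1", 10, S.INDEX_111, code="A"),  # duplicate index
        _row("p2", 0, S.PRIMARY_CARE),  # no index at all
        _row("p3", 0, S.INDEX_111, code="A"),
        _row("p3", 9000, S.ED),  # beyond 72 h
    ]
    violations = validate_event_log(_log(rows))
    assert any("p1" in v and "2" in v for v in violations)
    assert any("p2" in v for v in violations)
    assert any("p3" in v and "72" in v for v in violations)
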
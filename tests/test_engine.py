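"""Engine behaviour: arrivals, trajectories, caps, determinism, recounting."""

import math

import numpy as np
import pytest

from careflow import clock
from careflow.engine import (
    generate_arrivals,
    run_simulation,
    simulate_patient,
    write_event_log,
)
from careflow.errors import SimulationError
from careflow.fitting import FittedDistribution
from careflow.parameters import ServiceKind
from careflow.scenarios import BASE_SCENARIO

from conftest import make_tiny_bundle

S = ServiceKind


def test_all_infinite_rates_give_no_arrivals():
    rates = {s: math.inf for s in clock.all_strata()}
    assert generate_arrivals(rates, 7 * 1440.0, np.random.default_rng(0)) == []


def test_weekend_gating_blocks_weekend_arrivals():
    rates = {
        (h, q, wk): (math.inf if wk else 30.0)
        for (h, q, wk) in clock.all_strata()
    }
    arrivals = generate_arrivals(rates, 7 * 1440.0, np.random.default_rng(1))
    assert arrivals, "weekday arrivals expected"
    assert all(not clock.is_weekend(t) for t in arrivals)


def test_homogeneous_arrival_counts_match_poisson_mean():
    # small version of the closed-form check (full version in acceptance)
    rates = {s: 30.0 for s in clock.all_strata()}
    counts = [
        len(generate_arrivals(rates, 1440.0, np.random.default_rng(seed)))
        for seed in range(200)
    ]
    se = math.sqrt(48.0 / len(counts))
    assert np.mean(counts) == pytest.approx(48.0, abs=3 * se)


def test_immediate_exit_gives_single_event_record():
    bundle = make_tiny_bundle(index_row={S.NO_FURTHER_CONTACT: 1.0})
    rec = simulate_patient(100.0, bundle, BASE_SCENARIO, np.random.default_rng(0))
    assert len(rec.events) == 1
    assert rec.events[0].service is S.INDEX_111
    assert rec.first_contact is S.NO_FURTHER_CONTACT
    assert rec.gp_first_contact is False


def test_guaranteed_timely_first_contact_respects_timeframe():
    bundle = make_tiny_bundle(
        index_row={S.PRIMARY_CARE: 1.0},
        p_timely={"A": 1.0, "B": 1.0},
        queue_mean=500.0,  # typical draw far beyond either timeframe
    )
    timeframes = {"A": 120.0, "B": 360.0}
    for seed in range(100):
        rec = simulate_patient(0.0, bundle, BASE_SCENARIO, np.random.default_rng(seed))
        first = rec.events[1]
        assert first.service is S.PRIMARY_CARE
        assert first.service_start <= timeframes[rec.disposition_code]
        assert rec.timely


def test_cap_truncates_long_queues():
    bundle = make_tiny_bundle(
        index_row={S.PRIMARY_CARE: 1.0},
        pc_row_gp_true={S.ED: 1.0},
        p_timely={"A": 0.0, "B": 0.0},
    )
    # every queue draw is exactly 4000 min; the second hop would start
    # beyond the 72-h cap and must be discarded
    for key in bundle.queue_delays:
        bundle.queue_delays[key] = FittedDistribution("uniform", (4000.0, 0.0))
    rec = simulate_patient(0.0, bundle, BASE_SCENARIO, np.random.default_rng(2))
    assert [e.service for e in rec.events] == [S.INDEX_111, S.PRIMARY_CARE]
    assert all(e.service_start <= 4320.0 for e in rec.events)


def test_missing_delay_distribution_names_the_hop():
    bundle = make_tiny_bundle(index_row={S.ED: 1.0})
    del bundle.queue_delays[(S.INDEX_111, S.ED)]
    with pytest.raises(SimulationError, match="INDEX_111->ED"):
        simulate_patient(0.0, bundle, BASE_SCENARIO, np.random.default_rng(0))


def test_identical_seeds_reproduce_byte_identical_logs(tiny_bundle, tmp_path):
    for name in ("a.csv", "b.csv"):
        log, _ = run_simulation(tiny_bundle, BASE_SCENARIO, seed=99)
        write_event_log(log, tmp_path / name)
    assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()


def test_run_summary_equals_independent_recount(tiny_bundle):
    log, summary = run_simulation(tiny_bundle, BASE_SCENARIO, seed=5)
    # recount from the emitted log only
    assert summary.n_patients == (log["service"] == "INDEX_111").sum()
    recount: dict = {}
    for _, row in log.iterrows():
        key = (S(row["service"]), clock.quarter_of(float(row["timestamp"])))
        recount[key] = recount.get(key, 0) + 1
    assert recount == summary.counts
    totals = log["service"].value_counts().to_dict()
    assert {k.value: v for k, v in summary.totals.items()} == totals
    assert summary.avoidable_ed == (log["avoidable"] == "true").sum()
    assert summary.ed_attendances == (log["service"] == "ED").sum()
    # first-contact histogram from per-patient second rows
    first = {}
    for _pid, grp in log.groupby("patient_id", sort=False):
        svc = grp.iloc[1]["service"] if len(grp) > 1 else "NO_FURTHER_CONTACT"
        first[svc] = first.get(svc, 0) + 1
    assert {k.value: v for k, v in summary.first_contact.items() if v} == first
    assert sum(summary.first_contact.values()) == summary.n_patients


def test_no_event_starts_after_patient_cap(tiny_bundle):
    _log, _summary, patients = run_simulation(
        tiny_bundle, BASE_SCENARIO, seed=7, return_patients=True
    )
    for p in patients:
        assert p.events[0].service is S.INDEX_111
        assert p.events[0].service_start == p.arrival_time
        starts = [e.service_start for e in p.events]
        assert starts == sorted(starts)
        assert all(s <= p.arrival_time + 4320.0 for s in starts)


def test_raising_timely_proportion_never_loses_timely_contacts(tiny_bundle):
    """Common random numbers: p_timely up => timely first-PC count not down."""

    def timely_pc_count(p):
        bundle = make_tiny_bundle(p_timely={"A": p, "B": p})
        _log, _s, patients = run_simulation(
            bundle, BASE_SCENARIO, seed=11, return_patients=True
        )
        n = 0
        for rec in patients:
            if rec.gp_first_contact and rec.timely:
                tf = {"A": 120.0, "B": 360.0}[rec.disposition_code]
                if rec.events[1].service_start - rec.arrival_time <= tf:
                    n += 1
        return n

    counts = [timely_pc_count(p) for p in (0.2, 0.5, 0.9)]
    assert counts == sorted(counts)


def test_avoidable_flag_only_on_ed_events(tiny_bundle):
    log, _ = run_simulation(tiny_bundle, BASE_SCENARIO, seed=13)
    ed = log[log["service"] == "ED"]
    other = log[log["service"] != "ED"]
    assert set(ed["avoidable"]) <= {"true", "false"}
    assert set(other["avoidable"]) == {""}
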
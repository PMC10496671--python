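"""Replication, CI arithmetic, paired comparison and trajectory tables."""

import math

import numpy as np
import pandas as pd
import pytest

from careflow.engine import RunSummary
from careflow.parameters import ServiceKind
from careflow.reporting import (
    ReplicationSet,
    compare,
    derive_run_seeds,
    hourly_profile,
    mean_ci,
    percentage_ratio,
    proportion_pct,
    replicate,
    summarize,
    trajectory_table,
)
from careflow.scenarios import BASE_SCENARIO

from conftest import make_tiny_bundle

S = ServiceKind


def _summary_from_totals(run_id, totals, n_patients=100, avoidable=0, ed=None):
    totals = {S(k) if isinstance(k, str) else k: v for k, v in totals.items()}
    ed_count = ed if ed is not None else totals.get(S.ED, 0)
    return RunSummary(
        run_id=run_id,
        seed=0,
        n_patients=n_patients,
        counts={(s, 1): c for s, c in totals.items()},
        totals=totals,
        first_contact={S.NO_FURTHER_CONTACT: n_patients},
        avoidable_ed=avoidable,
        ed_attendances=ed_count,
    )


def repset_from_counts(label, per_run_totals, **kw):
    return ReplicationSet(
        label=label,
        master_seed=0,
        summaries=[
            _summary_from_totals(f"{label}-{i}", totals, **kw)
            for i, totals in enumerate(per_run_totals)
        ],
    )


def test_mean_ci_closed_form():
    m, lo, hi = mean_ci([10, 12, 14])
    assert m == pytest.approx(12.0)
    half = 1.96 * 2.0 / math.sqrt(3)
    assert lo == pytest.approx(12.0 - half)
    assert hi == pytest.approx(12.0 + half)


def test_equal_runs_give_zero_width_ci():
    m, lo, hi = mean_ci([5.0, 5.0, 5.0, 5.0])
    assert (m, lo, hi) == (5.0, 5.0, 5.0)


def test_replicate_is_deterministic_and_seeds_distinct(tiny_bundle):
    a = replicate(tiny_bundle, BASE_SCENARIO, n_runs=2, master_seed=42)
    b = replicate(tiny_bundle, BASE_SCENARIO, n_runs=2, master_seed=42)
    assert a.seeds == b.seeds
    for ra, rb in zip(a.summaries, b.summaries):
        assert ra.totals == rb.totals
        assert ra.counts == rb.counts
    assert len(set(derive_run_seeds(0, 100))) == 100
    assert all(0 <= s < 2**31 for s in derive_run_seeds(0, 100))


def test_deterministic_bundle_yields_zero_width_cis():
    bundle = make_tiny_bundle(
        arrival_mean=math.inf, index_row={S.NO_FURTHER_CONTACT: 1.0}
    )
    # no arrivals at all: every run identical, every CI degenerate
    reps = replicate(bundle, BASE_SCENARIO, n_runs=3, master_seed=1)
    table = summarize(reps)
    counts = table[table["metric"].str.contains("total|quarterly|count|n_patients")]
    assert (counts["ci_upper"] - counts["ci_lower"]).abs().max() == 0.0
    # proportion metrics are undefined (0/0) with no callers, hence NaN
    defined = table.dropna(subset=["mean"])
    assert (defined["ci_upper"] - defined["ci_lower"]).abs().max() == 0.0


def test_compare_with_itself_is_identity(tiny_bundle):
    reps = replicate(tiny_bundle, BASE_SCENARIO, n_runs=3, master_seed=5)
    report = compare(reps, reps)
    assert np.allclose(report.services["diff_mean"], 0.0)
    active = report.services.dropna(subset=["pct_change_mean"])
    assert np.allclose(active["pct_change_mean"], 100.0)
    assert (report.services["base_ci_lower"] <= report.services["base_mean"]).all()
    assert (report.services["base_mean"] <= report.services["base_ci_upper"]).all()


def test_zero_base_count_yields_nan_pct_with_warning():
    base = repset_from_counts("base", [{"ED": 0}, {"ED": 4}])
    whatif = repset_from_counts("what-if", [{"ED": 1}, {"ED": 2}])
    with pytest.warns(UserWarning, match="percentage change undefined"):
        report = compare(base, whatif)
    ed = report.services.set_index("service").loc["Emergency department"]
    assert math.isnan(ed["pct_change_mean"])


def test_percentage_change_is_ratio_scale():
    assert percentage_ratio(39283, 77030) == pytest.approx(196.1, abs=0.05)
    assert percentage_ratio(100, 100) == 100.0
    assert proportion_pct(1029, 9290) == pytest.approx(11.1, abs=0.05)
    assert math.isnan(percentage_ratio(0, 5))


def test_mismatched_replication_sizes_raise():
    a = repset_from_counts("base", [{"ED": 1}])
    b = repset_from_counts("what-if", [{"ED": 1}, {"ED": 2}])
    with pytest.raises(ValueError):
        compare(a, b)


def test_ci_coverage_of_known_mean():
    """95% normal CI should cover the true mean ~95% of the time."""
    rng = np.random.default_rng(2024)
    true_mean, sd, n_runs = 100.0, 15.0, 30
    covered = 0
    meta = 200
    for _ in range(meta):
        _m, lo, hi = mean_ci(rng.normal(true_mean, sd, n_runs))
        covered += lo <= true_mean <= hi
    assert 0.90 * meta <= covered <= 0.99 * meta


# --- trajectory and hourly tables --------------------------------------------

def _log(rows):
    return pd.DataFrame(rows, columns=["patient_id", "timestamp", "service"])


def test_index_only_patient_chain():
    table = trajectory_table(_log([("p1", 0.0, "INDEX_111")]))
    assert table.iloc[0]["chain"] == "INDEX_111 > NO_FURTHER_CONTACT"
    assert table.iloc[0]["count"] == 1


def test_hand_built_chains_tally():
    rows = [
        ("p1", 0.0, "INDEX_111"), ("p1", 10.0, "PRIMARY_CARE"),
        ("p2", 1.0, "INDEX_111"), ("p2", 11.0, "PRIMARY_CARE"),
        ("p3", 2.0, "INDEX_111"), ("p3", 12.0, "ED"), ("p3", 20.0, "INPATIENT"),
    ]
    table = trajectory_table(_log(rows), depth=5)
    counts = dict(zip(table["chain"], table["count"]))
    assert counts == {
        "INDEX_111 > PRIMARY_CARE > NO_FURTHER_CONTACT": 2,
        "INDEX_111 > ED > INPATIENT > NO_FURTHER_CONTACT": 1,
    }
    assert table["count"].sum() == 3


def test_chain_counts_conserve_patients(tiny_bundle):
    from careflow.engine import run_simulation

    log, summary = run_simulation(tiny_bundle, BASE_SCENARIO, seed=17)
    table = trajectory_table(log)
    assert table["count"].sum() == summary.n_patients


def test_depth_truncation_has_no_padding():
    rows = [("p1", float(i), s) for i, s in enumerate(
        ["INDEX_111", "PRIMARY_CARE", "ED", "INPATIENT", "PRIMARY_CARE", "ED"]
    )]
    table = trajectory_table(_log(rows), depth=3)
    assert table.iloc[0]["chain"] == "INDEX_111 > PRIMARY_CARE > ED"


def test_hourly_profile_empty_log_is_all_zero():
    table = hourly_profile(_log([]))
    assert len(table) == 48
    assert table["count"].sum() == 0


def test_hourly_profile_calendar_mapping():
    # t = 90 min on day 0 (a Friday): hour 1, weekday
    table = hourly_profile(_log([("p1", 90.0, "INDEX_111")]))
    row = table[(table["hour"] == 1) & (~table["is_weekend"])]
    assert row["count"].iloc[0] == 1
    assert table["count"].sum() == 1


def test_hourly_profile_recount_matches_simulated_log(tiny_bundle):
    from careflow.engine import run_simulation
    from careflow import clock

    log, summary = run_simulation(tiny_bundle, BASE_SCENARIO, seed=19)
    table = hourly_profile(log)
    assert table["count"].sum() == summary.n_patients
    index_rows = log[log["service"] == "INDEX_111"]
    manual = {}
    for t in index_rows["timestamp"]:
        key = (clock.hour_of(t), clock.is_weekend(t))
        manual[key] = manual.get(key, 0) + 1
    for (h, wk), c in manual.items():
        got = table[(table["hour"] == h) & (table["is_weekend"] == wk)]["count"].iloc[0]
        assert got == c
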
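"""Shared fixtures: a small fast bundle plus the session-scoped synthetic
ground truth, its one-year event log and the bundle re-estimated from it."""

from __future__ import annotations

import pytest

from careflow import clock
from careflow.estimation import estimate_bundle
from careflow.fitting import FittedDistribution
from careflow.parameters import (
    DispositionSpec,
    ParameterBundle,
    ServiceKind,
    TRANSITION_SOURCES,
    validate_bundle,
)
from careflow.synthetic import generate_log, make_default_truth

S = ServiceKind


def make_tiny_bundle(
    arrival_mean: float = 30.0,
    horizon_days: float = 7.0,
    index_row: dict | None = None,
    pc_row_gp_true: dict | None = None,
    pc_row_gp_false: dict | None = None,
    p_timely: dict | None = None,
    queue_mean: float = 30.0,
) -> ParameterBundle:
    """A two-disposition bundle small enough for fast exact checks.

    Only INDEX_111 -> {PRIMARY_CARE, ED, exit} and PRIMARY_CARE ->
    {PRIMARY_CARE, ED, exit} hops are reachable; all other services
    absorb immediately.
    """
    index_row = index_row or {S.PRIMARY_CARE: 0.5, S.ED: 0.2, S.NO_FURTHER_CONTACT: 0.3}
    pc_true = pc_row_gp_true or {S.PRIMARY_CARE: 0.1, S.ED: 0.1, S.NO_FURTHER_CONTACT: 0.8}
    pc_false = pc_row_gp_false or {S.PRIMARY_CARE: 0.1, S.ED: 0.3, S.NO_FURTHER_CONTACT: 0.6}
    absorb = {S.NO_FURTHER_CONTACT: 1.0}
    transitions = {}
    for src in TRANSITION_SOURCES:
        for gp in (False, True):
            for quarter in (1, 2, 3, 4):
                if src is S.INDEX_111:
                    row = index_row
                elif src is S.PRIMARY_CARE:
                    row = pc_true if gp else pc_false
                else:
                    row = absorb
                transitions[(src, gp, quarter)] = dict(row)
    queue = FittedDistribution("exponential", (queue_mean,))
    queue_delays = {
        (src, dest): queue
        for src in (S.INDEX_111, S.PRIMARY_CARE, S.ED)
        for dest in (S.PRIMARY_CARE, S.ED)
    }
    bundle = ParameterBundle(
        arrival_rates={s: arrival_mean for s in clock.all_strata()},
        dispositions=[
            DispositionSpec("A", 120, "remote", 0.6),
            DispositionSpec("B", 360, "face_to_face", 0.4),
        ],
        timely=dict(p_timely or {"A": 0.5, "B": 0.8}),
        transitions=transitions,
        queue_delays=queue_delays,
        activity_delays={
            S.INDEX_111: FittedDistribution("uniform", (0.0, 0.0)),
            S.PRIMARY_CARE: FittedDistribution("uniform", (5.0, 10.0)),
            S.ED: FittedDistribution("uniform", (10.0, 20.0)),
        },
        avoidable={(c, gp): p for c, p in (("A", 0.25), ("B", 0.5)) for gp in (False, True)},
        horizon_minutes=horizon_days * clock.MINUTES_PER_DAY,
    )
    assert validate_bundle(bundle) == []
    return bundle


@pytest.fixture
def tiny_bundle() -> ParameterBundle:
    return make_tiny_bundle()


@pytest.fixture(scope="session")
def truth():
    return make_default_truth(seed=1)


@pytest.fixture(scope="session")
def synthetic_year_log(truth):
    """One simulated year under the ground truth (~56k callers)."""
    return generate_log(truth)


@pytest.fixture(scope="session")
def recovered_bundle(truth, synthetic_year_log):
    """Bundle re-estimated from the synthetic year, for recovery checks."""
    return estimate_bundle(synthetic_year_log, truth.bundle.dispositions)
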
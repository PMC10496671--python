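"""Core discrete event simulation.

One run generates index 111 calls over the horizon from a non-stationary
exponential arrival process, then walks each caller independently through
the healthcare system for at most 72 hours: disposition allocation, a
timely-contact draw, and a transition-probability walk with queue and
activity durations sampled from the bundle's fitted distributions.

Callers are mutually independent (the system carries no capacity
constraints), so each patient gets a dedicated child random stream
derived from the run seed.  This makes runs reproducible bit-for-bit and
makes per-patient trajectories invariant to what other patients do —
which is what lets common-random-number scenario comparisons couple
cleanly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import clock
from .errors import SimulationError
from .fitting import sample_duration
from .parameters import ParameterBundle, ServiceKind
from .scenarios import ScenarioFlags, BASE_SCENARIO

#: Attempts at conditioning the first-hop queue draw before falling back.
_TIMELY_REJECT_LIMIT = 1000

EVENT_LOG_COLUMNS = [
    "patient_id",
    "timestamp",
    "service",
    "disposition_code",
    "queue_start",
    "end_timestamp",
    "avoidable",
]


@dataclass(frozen=True)
class EventRecord:
    """One service contact inside a patient's trajectory."""

    service: ServiceKind
    queue_start: float
    service_start: float
    service_end: float
    avoidable: bool | None = None  # populated iff service is ED


@dataclass
class PatientRecord:
    """One simulated caller and their ordered 72-hour trajectory."""

    patient_id: str
    arrival_time: float
    disposition_code: str
    timely: bool
    gp_first_contact: bool
    events: list[EventRecord] = field(default_factory=list)

    @property
    def first_contact(self) -> ServiceKind:
        """Service of the first post-index contact (or NO_FURTHER_CONTACT)."""
        if len(self.events) < 2:
            return ServiceKind.NO_FURTHER_CONTACT
        return self.events[1].service


@dataclass
class RunSummary:
    """Aggregate counts for one run, recomputable from its event log."""

    run_id: str
    seed: int
    n_patients: int
    counts: dict  # (ServiceKind, quarter) -> int
    totals: dict  # ServiceKind -> int
    first_contact: dict  # ServiceKind -> int (incl. NO_FURTHER_CONTACT)
    avoidable_ed: int
    ed_attendances: int

    def to_counts_frame(self) -> pd.DataFrame:
        rows = [
            {"run_id": self.run_id, "seed": self.seed, "service": s.value,
             "quarter": q, "count": c}
            for (s, q), c in sorted(self.counts.items(), key=lambda kv: str(kv[0]))
        ]
        return pd.DataFrame(rows, columns=["run_id", "seed", "service", "quarter", "count"])

    def to_first_contact_frame(self) -> pd.DataFrame:
        rows = [
            {"run_id": self.run_id, "seed": self.seed, "service": s.value, "count": c}
            for s, c in sorted(self.first_contact.items(), key=lambda kv: str(kv[0]))
        ]
        return pd.DataFrame(rows, columns=["run_id", "seed", "service", "count"])


class _CompiledBundle:
    """Bundle pre-processed for fast repeated sampling."""

    def __init__(self, bundle: ParameterBundle):
        self.bundle = bundle
        weights = np.array([d.weight for d in bundle.dispositions], dtype=float)
        self.dispo_codes = [d.code for d in bundle.dispositions]
        self.dispo_cum = np.cumsum(weights / weights.sum())
        self.timeframe = {d.code: float(d.timeframe_minutes) for d in bundle.dispositions}
        self.p_timely = dict(bundle.timely)
        self.p_avoidable = dict(bundle.avoidable)
        self.transitions = {}
        for key, row in bundle.transitions.items():
            dests = sorted(row, key=lambda s: s.value)
            probs = np.array([row[d] for d in dests], dtype=float)
            total = probs.sum()
            self.transitions[key] = (dests, np.cumsum(probs / total))
        self.queue = dict(bundle.queue_delays)
        self.activity = dict(bundle.activity_delays)
        self.cap = float(bundle.patient_cap_minutes)

    def draw_disposition(self, rng) -> str:
        return self.dispo_codes[int(np.searchsorted(self.dispo_cum, rng.random()))]

    def draw_destination(self, key, rng) -> ServiceKind:
        try:
            dests, cum = self.transitions[key]
        except KeyError:
            raise SimulationError(f"no transition row for {key}") from None
        return dests[int(np.searchsorted(cum, rng.random()))]

    def draw_queue(self, src: ServiceKind, dest: ServiceKind, rng) -> float:
        try:
            dist = self.queue[(src, dest)]
        except KeyError:
            raise SimulationError(
                f"no queue-delay distribution for hop {src}->{dest}"
            ) from None
        return sample_duration(dist, rng)

    def draw_activity(self, service: ServiceKind, rng) -> float:
        if service is ServiceKind.INDEX_111 and service not in self.activity:
            return 0.0  # index call duration optional
        try:
            dist = self.activity[service]
        except KeyError:
            raise SimulationError(
                f"no activity-duration distribution for service {service}"
            ) from None
        return sample_duration(dist, rng)


def generate_arrivals(
    arrival_rates: dict,
    horizon_minutes: float,
    rng: np.random.Generator,
    start_weekday: int = clock.DEFAULT_START_WEEKDAY,
    method: str = "thinning",
) -> list[float]:
    """Index-call arrival times over [0, horizon) from stratified rates.

    The default ``thinning`` method draws a homogeneous exponential
    stream at the fastest stratum's rate and accepts each candidate with
    probability rate(t)/rate_max — exact for a piecewise-constant
    intensity, and exactly Poisson when all strata share one rate.

    ``stratum_of_draw`` instead draws each gap from the stratum the clock
    is in when the draw is made, accepting gaps that cross into another
    finite-rate stratum as-is.  It is cheaper but undercounts the start
    of any hour whose rate jumps sharply upward (the residual gap is
    drawn at the slower rate), so it is kept only for comparison.

    Under either method an infinite mean encodes a zero-rate stratum:
    no arrival can fall inside it.
    """
    if method == "thinning":
        lam_max = max(
            (1.0 / m for m in arrival_rates.values() if not math.isinf(m)),
            default=0.0,
        )
        if lam_max == 0.0:
            return []
        out: list[float] = []
        t = 0.0
        while True:
            t += rng.exponential(1.0 / lam_max)
            if t >= horizon_minutes:
                return out
            mean = arrival_rates[clock.stratum_of(t, start_weekday)]
            if not math.isinf(mean) and rng.random() * lam_max <= 1.0 / mean:
                out.append(t)
    if method != "stratum_of_draw":
        raise ValueError(f"unknown arrival method {method!r}")
    t = 0.0
    out = []
    while t < horizon_minutes:
        mean = arrival_rates[clock.stratum_of(t, start_weekday)]
        if math.isinf(mean):
            t = clock.next_hour_boundary(t)
            continue
        t += rng.exponential(mean)
        if t < horizon_minutes and not math.isinf(
            arrival_rates[clock.stratum_of(t, start_weekday)]
        ):
            out.append(t)
    return out


def _conditioned_first_queue(
    compiled: _CompiledBundle,
    src: ServiceKind,
    dest: ServiceKind,
    queue_start: float,
    deadline: float,
    timely: bool,
    timeframe: float,
    rng: np.random.Generator,
) -> float:
    """First-hop queue draw conditioned on the timely flag.

    ``deadline`` is (index call time + disposition timeframe).  A timely
    caller's primary-care contact must start by the deadline; a
    non-timely caller's must start after it.  Rejection sampling keeps
    the queue distribution's shape; after 1000 failed attempts the draw
    falls back to a uniform draw on the feasible side.
    """
    budget = deadline - queue_start
    if timely:
        if budget <= 0:
            return 0.0  # timeframe already exhausted by the index call itself
        for _ in range(_TIMELY_REJECT_LIMIT):
            q = compiled.draw_queue(src, dest, rng)
            if q <= budget:
                return q
        return rng.uniform(0.0, budget)
    for _ in range(_TIMELY_REJECT_LIMIT):
        q = compiled.draw_queue(src, dest, rng)
        if q > budget:
            return q
    return max(budget, 0.0) + rng.uniform(0.0, timeframe)


def simulate_patient(
    arrival_time: float,
    bundle: ParameterBundle | _CompiledBundle,
    scenario_flags: ScenarioFlags,
    rng: np.random.Generator,
    patient_id: str = "p0",
) -> PatientRecord:
    """Walk one caller's stochastic trajectory for up to 72 hours."""
    compiled = bundle if isinstance(bundle, _CompiledBundle) else _CompiledBundle(bundle)

    code = compiled.draw_disposition(rng)
    timely = rng.random() < compiled.p_timely[code]
    quarter = clock.quarter_of(arrival_time)
    timeframe = compiled.timeframe[code]
    deadline = arrival_time + timeframe

    index_activity = compiled.draw_activity(ServiceKind.INDEX_111, rng)
    events = [
        EventRecord(ServiceKind.INDEX_111, arrival_time, arrival_time,
                    arrival_time + index_activity)
    ]
    current = ServiceKind.INDEX_111
    now = events[0].service_end
    gp_first = False
    first_hop = True
    cap_end = arrival_time + compiled.cap

    while True:
        if first_hop and scenario_flags.force_primary_care_first:
            dest = ServiceKind.PRIMARY_CARE
        else:
            # The first transition is drawn from the marginal INDEX_111 row
            # (stored under gp_first_contact=False); it *defines* the flag.
            dest = compiled.draw_destination((current, gp_first, quarter), rng)
        if dest is ServiceKind.NO_FURTHER_CONTACT:
            break

        if first_hop and dest is ServiceKind.PRIMARY_CARE:
            queue = _conditioned_first_queue(
                compiled, current, dest, now, deadline, timely, timeframe, rng
            )
        else:
            queue = compiled.draw_queue(current, dest, rng)

        service_start = now + queue
        if service_start > cap_end:
            break  # event discarded; patient exits at the 72-h cap

        if first_hop:
            gp_first = dest is ServiceKind.PRIMARY_CARE
            first_hop = False

        activity = compiled.draw_activity(dest, rng)
        avoidable = None
        if dest is ServiceKind.ED:
            avoidable = rng.random() < compiled.p_avoidable[(code, gp_first)]
        events.append(
            EventRecord(dest, now, service_start, service_start + activity, avoidable)
        )
        current = dest
        now = service_start + activity

    return PatientRecord(
        patient_id=patient_id,
        arrival_time=arrival_time,
        disposition_code=code,
        timely=timely,
        gp_first_contact=gp_first,
        events=events,
    )


def _summarise(patients: list[PatientRecord], run_id: str, seed: int) -> RunSummary:
    counts: dict = {}
    totals: dict = {}
    first_contact = {s: 0 for s in ServiceKind if s is not ServiceKind.INDEX_111}
    avoidable_ed = 0
    ed_attendances = 0
    for p in patients:
        first_contact[p.first_contact] += 1
        for ev in p.events:
            q = clock.quarter_of(ev.service_start)
            counts[(ev.service, q)] = counts.get((ev.service, q), 0) + 1
            totals[ev.service] = totals.get(ev.service, 0) + 1
            if ev.service is ServiceKind.ED:
                ed_attendances += 1
                if ev.avoidable:
                    avoidable_ed += 1
    return RunSummary(
        run_id=run_id,
        seed=seed,
        n_patients=len(patients),
        counts=counts,
        totals=totals,
        first_contact=first_contact,
        avoidable_ed=avoidable_ed,
        ed_attendances=ed_attendances,
    )


def patients_to_event_log(patients: list[PatientRecord]) -> pd.DataFrame:
    """Flatten patient records into the tidy event-log table."""
    rows = []
    for p in patients:
        for i, ev in enumerate(p.events):
            rows.append(
                (
                    p.patient_id,
                    ev.service_start,
                    ev.service.value,
                    p.disposition_code if i == 0 else "",
                    ev.queue_start,
                    ev.service_end,
                    "" if ev.avoidable is None else ("true" if ev.avoidable else "false"),
                )
            )
    return pd.DataFrame(rows, columns=EVENT_LOG_COLUMNS)


def run_simulation(
    bundle: ParameterBundle,
    scenario_flags: ScenarioFlags = BASE_SCENARIO,
    seed: int = 0,
    run_id: str | None = None,
    return_patients: bool = False,
):
    """One full run: arrivals over the horizon, then every trajectory.

    Returns ``(event_log, run_summary)`` — or ``(event_log, run_summary,
    patients)`` with ``return_patients=True``.  Deterministic given
    (bundle, scenario_flags, seed).
    """
    compiled = _CompiledBundle(bundle)
    root = np.random.SeedSequence(seed)
    arrival_ss, patient_ss = root.spawn(2)
    arrivals = generate_arrivals(
        bundle.arrival_rates,
        bundle.horizon_minutes,
        np.random.default_rng(arrival_ss),
        bundle.start_weekday,
    )
    width = max(6, len(str(len(arrivals))))
    patients = []
    for i, (t, child) in enumerate(zip(arrivals, patient_ss.spawn(len(arrivals)))):
        patients.append(
            simulate_patient(
                t, compiled, scenario_flags, np.random.default_rng(child),
                patient_id=f"p{i:0{width}d}",
            )
        )
    summary = _summarise(patients, run_id or f"run-{seed}", seed)
    log = patients_to_event_log(patients)
    if return_patients:
        return log, summary, patients
    return log, summary


def write_event_log(log: pd.DataFrame, path) -> None:
    """Write an event log CSV with stable float formatting."""
    log.to_csv(path, index=False, float_format="%.6f")
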
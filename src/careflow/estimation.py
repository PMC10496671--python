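"""Estimate every model parameter from a linked patient-level event log.

The log is a tidy table of service contacts — one row per contact, keyed
by a pseudonymous patient id — covering the index 111 call and everything
the patient touched in the following 72 hours.  Each estimator mirrors
the corresponding sampling step in the engine, so a log simulated from a
known bundle recovers that bundle (the round-trip property the test
suite leans on).

Avoidable ED attendance follows the O'Keeffe criteria: a type 1 ED
attendance (consultant-led, 24-hour, full resuscitation facilities) in
which the patient received no investigations, treatments or referral
requiring those facilities.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from . import clock
from .errors import ClassificationError, EstimationError
from .fitting import DEFAULT_CANDIDATES, FittedDistribution, fit_distribution, FitError
from .parameters import (
    DispositionSpec,
    ParameterBundle,
    ServiceKind,
    TRANSITION_SOURCES,
    QUARTERS,
)

EVENT_LOG_CSV_COLUMNS = [
    "patient_id",
    "timestamp",
    "service",
    "disposition_code",
    "ed_investigations",
    "ed_treatments",
    "ed_referral",
    "is_type1_ed",
    "end_timestamp",
]

_FLAG_COLUMNS = ("ed_investigations", "ed_treatments", "ed_referral", "is_type1_ed")


def _as_bool(value):
    """Parse a log boolean; None for missing/empty."""
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    text = str(value).strip().lower()
    if text in ("true", "1", "t", "yes"):
        return True
    if text in ("false", "0", "f", "no"):
        return False
    if text == "":
        return None
    raise ClassificationError(f"unparseable boolean flag: {value!r}")


def classify_avoidable(ed_row) -> bool:
    """O'Keeffe classification of one ED attendance row.

    True iff the attendance was at a type 1 ED and used none of the
    type-1 resources (investigations, treatments, referral).
    """
    flags = {}
    for col in _FLAG_COLUMNS:
        try:
            raw = ed_row[col]
        except (KeyError, IndexError):
            raise ClassificationError(f"ED row missing flag {col!r}") from None
        parsed = _as_bool(raw)
        if parsed is None:
            raise ClassificationError(f"ED row flag {col!r} is missing/empty")
        flags[col] = parsed
    if not flags["is_type1_ed"]:
        return False
    return not (
        flags["ed_investigations"] or flags["ed_treatments"] or flags["ed_referral"]
    )


def load_event_log(path) -> pd.DataFrame:
    """Read an event-log CSV (timestamps in model minutes or ISO-8601)."""
    df = pd.read_csv(path, dtype={"patient_id": str}, keep_default_na=False)
    missing = [c for c in ("patient_id", "timestamp", "service") if c not in df.columns]
    if missing:
        raise EstimationError(f"event log {path} missing columns: {missing}")
    for col in ("timestamp", "end_timestamp"):
        if col in df.columns:
            df[col] = _to_minutes(df[col])
    return df


def _to_minutes(series: pd.Series) -> pd.Series:
    """Convert a timestamp column to model minutes.

    Numeric values pass through; ISO-8601 datetimes are measured from
    midnight on 1 January of the log's first year.
    """
    blank = series.astype(str).str.strip() == ""
    numeric = pd.to_numeric(series.mask(blank), errors="coerce")
    if numeric.notna().sum() >= (~blank & series.notna()).sum():
        return numeric
    stamps = pd.to_datetime(series.mask(blank), errors="coerce")
    origin = stamps.min().replace(month=1, day=1, hour=0, minute=0, second=0)
    return (stamps - origin).dt.total_seconds() / 60.0


def validate_event_log(log: pd.DataFrame, cap_minutes: float = 4320.0) -> list[str]:
    """Check EventLog invariants; returns violation messages."""
    v: list[str] = []
    known = {s.value for s in ServiceKind}
    bad = sorted(set(log["service"]) - known)
    if bad:
        v.append(f"unknown service codes: {bad}")
    index_rows = log[log["service"] == ServiceKind.INDEX_111.value]
    per_patient = index_rows.groupby("patient_id").size()
    for pid, n in per_patient[per_patient != 1].items():
        v.append(f"patient {pid} has {n} INDEX_111 rows (expected exactly 1)")
    no_index = set(log["patient_id"]) - set(index_rows["patient_id"])
    for pid in sorted(no_index):
        v.append(f"patient {pid} has no INDEX_111 row")
    # first index timestamp per patient (duplicates already reported above)
    index_time = index_rows.groupby("patient_id")["timestamp"].min()
    for pid, grp in log.groupby("patient_id"):
        if pid in no_index:
            continue
        t = grp["timestamp"].to_numpy(float)
        if np.any(np.diff(t) < 0):
            v.append(f"patient {pid} rows are not time-ordered")
        if np.any(t - float(index_time[pid]) > cap_minutes):
            v.append(f"patient {pid} has contacts beyond the 72-h window")
        if np.any(t < float(index_time[pid])):
            v.append(f"patient {pid} has contacts before the index call")
    return v


def _patient_trajectories(log: pd.DataFrame):
    """Yield (patient_id, index_row, ordered non-index rows) per patient."""
    ordered = log.sort_values(["patient_id", "timestamp"], kind="mergesort")
    for pid, grp in ordered.groupby("patient_id", sort=False):
        index_mask = grp["service"] == ServiceKind.INDEX_111.value
        if not index_mask.any():
            continue
        idx_row = grp[index_mask].iloc[0]
        rest = grp[~index_mask]
        yield pid, idx_row, rest


def estimate_arrival_rates(
    log: pd.DataFrame,
    span_minutes: float = float(clock.MINUTES_PER_YEAR),
    start_weekday: int = clock.DEFAULT_START_WEEKDAY,
) -> dict:
    """Mean inter-arrival minutes per stratum from index-call timestamps.

    mean = (minutes the stratum was live over the span) / (index calls in
    the stratum); a stratum with no calls gets ``+inf``.
    """
    index_rows = log[log["service"] == ServiceKind.INDEX_111.value]
    if len(index_rows) == 0:
        raise EstimationError("event log contains no index 111 calls")
    if span_minutes < 90 * clock.MINUTES_PER_DAY:
        raise EstimationError("log span must cover at least one full calendar quarter")
    exposure = clock.stratum_exposure_minutes(span_minutes, start_weekday)
    counts = {s: 0 for s in exposure}
    for t in index_rows["timestamp"].to_numpy(float):
        counts[clock.stratum_of(t, start_weekday)] += 1
    rates = {}
    uncovered_quarters = set()
    for stratum, minutes in exposure.items():
        n = counts[stratum]
        if n == 0 or minutes == 0:
            rates[stratum] = math.inf
            uncovered_quarters.add(stratum[1])
        else:
            rates[stratum] = minutes / n
    covered = {s[1] for s, m in rates.items() if math.isfinite(m)}
    fully_uncovered = sorted(set(QUARTERS) - covered)
    if fully_uncovered:
        warnings.warn(
            f"no index calls observed in quarters {fully_uncovered}; "
            "their strata default to +inf (no arrivals)",
            stacklevel=2,
        )
    return rates


def _gp_first(rest: pd.DataFrame) -> bool:
    if len(rest) == 0:
        return False
    return rest.iloc[0]["service"] == ServiceKind.PRIMARY_CARE.value


def estimate_transitions(log: pd.DataFrame) -> tuple[dict, dict]:
    """Empirical next-service distributions.

    Returns ``(transitions, provenance)``.  Rows are keyed by
    (current service, gp_first_contact, quarter of the index call); the
    absence of any further event inside the 72-hour window is tallied as
    NO_FURTHER_CONTACT.  The INDEX_111 row receives the *marginal*
    first-contact distribution under both gp strata (the first transition
    defines the flag, so conditioning on it is circular).  Rows with no
    observations fall back to the same service pooled over strata, then
    to an absorbing exit; every fallback is recorded in provenance.
    """
    counts: dict = {}

    def tally(src: ServiceKind, gp: bool, quarter: int, dest: ServiceKind):
        row = counts.setdefault((src, gp, quarter), {})
        row[dest] = row.get(dest, 0) + 1

    for _pid, idx_row, rest in _patient_trajectories(log):
        quarter = clock.quarter_of(float(idx_row["timestamp"]))
        gp = _gp_first(rest)
        services = [ServiceKind(idx_row["service"])] + [
            ServiceKind(s) for s in rest["service"]
        ]
        chain = services + [ServiceKind.NO_FURTHER_CONTACT]
        for src, dest in zip(chain[:-1], chain[1:]):
            tally(src, gp, quarter, dest)

    # INDEX_111: replace both gp strata with the pooled (marginal) row.
    for quarter in QUARTERS:
        merged: dict = {}
        for gp in (False, True):
            for dest, n in counts.get((ServiceKind.INDEX_111, gp, quarter), {}).items():
                merged[dest] = merged.get(dest, 0) + n
        for gp in (False, True):
            if merged:
                counts[(ServiceKind.INDEX_111, gp, quarter)] = dict(merged)

    transitions: dict = {}
    provenance = {"transition_fallbacks": []}
    for src in TRANSITION_SOURCES:
        pooled_all: dict = {}
        pooled_by_gp = {False: {}, True: {}}
        for (s, gp, q), row in counts.items():
            if s is not src:
                continue
            for dest, n in row.items():
                pooled_all[dest] = pooled_all.get(dest, 0) + n
                pooled_by_gp[gp][dest] = pooled_by_gp[gp].get(dest, 0) + n
        for gp in (False, True):
            for quarter in QUARTERS:
                key = (src, gp, quarter)
                row = counts.get(key)
                if not row:
                    if pooled_by_gp[gp]:
                        row = pooled_by_gp[gp]
                        provenance["transition_fallbacks"].append(
                            f"{src.value}/gp={gp}/q{quarter}: pooled over quarters"
                        )
                    elif pooled_all:
                        row = pooled_all
                        provenance["transition_fallbacks"].append(
                            f"{src.value}/gp={gp}/q{quarter}: pooled over all strata"
                        )
                    else:
                        row = {ServiceKind.NO_FURTHER_CONTACT: 1}
                        provenance["transition_fallbacks"].append(
                            f"{src.value}/gp={gp}/q{quarter}: no observations; absorbing exit"
                        )
                total = sum(row.values())
                transitions[key] = {dest: n / total for dest, n in sorted(
                    row.items(), key=lambda kv: kv[0].value
                )}
    return transitions, provenance


def estimate_disposition_weights(log: pd.DataFrame) -> dict[str, float]:
    """Disposition code frequencies among index calls."""
    index_rows = log[log["service"] == ServiceKind.INDEX_111.value]
    if len(index_rows) == 0:
        raise EstimationError("event log contains no index 111 calls")
    codes = index_rows["disposition_code"].astype(str).str.strip()
    if (codes == "").any():
        raise EstimationError("index rows with empty disposition_code")
    freq = codes.value_counts(normalize=True)
    return {code: float(p) for code, p in freq.items()}


def estimate_timely_proportions(
    log: pd.DataFrame,
    timeframes: dict[str, float],
    among: str = "pc_first",
) -> dict[str, float]:
    """Proportion of timely primary-care contacts per disposition code.

    ``among="pc_first"`` (default) conditions on callers whose first
    post-index contact is primary care — the population over which the
    engine's timely mechanism acts, so simulation and estimation agree.
    ``among="all"`` divides by all callers with the code, counting callers
    who never reach primary care as not timely.
    """
    if among not in ("pc_first", "all"):
        raise ValueError("among must be 'pc_first' or 'all'")
    timely_counts: dict[str, int] = {}
    denom_counts: dict[str, int] = {}
    for _pid, idx_row, rest in _patient_trajectories(log):
        code = str(idx_row["disposition_code"]).strip()
        if code not in timeframes:
            raise EstimationError(f"disposition code {code!r} has no timeframe")
        t0 = float(idx_row["timestamp"])
        if among == "pc_first":
            if not _gp_first(rest):
                continue
            first_pc_time = float(rest.iloc[0]["timestamp"])
        else:
            pc = rest[rest["service"] == ServiceKind.PRIMARY_CARE.value]
            first_pc_time = float(pc.iloc[0]["timestamp"]) if len(pc) else math.inf
        denom_counts[code] = denom_counts.get(code, 0) + 1
        if first_pc_time - t0 <= timeframes[code]:
            timely_counts[code] = timely_counts.get(code, 0) + 1
    out = {}
    for code in timeframes:
        denom = denom_counts.get(code, 0)
        out[code] = timely_counts.get(code, 0) / denom if denom else 0.0
    return out


def estimate_avoidable_proportions(
    log: pd.DataFrame,
) -> tuple[dict, dict]:
    """Avoidable-ED proportion per (disposition code, gp_first_contact).

    Returns ``(table, info)``; ``info`` carries the pooled proportion, the
    number of ED rows that could not be classified (excluded), and which
    strata fell back to the code's pooled value.
    """
    num: dict = {}
    den: dict = {}
    pooled_num = pooled_den = 0
    per_code_num: dict[str, int] = {}
    per_code_den: dict[str, int] = {}
    n_unclassifiable = 0
    codes_seen: set[str] = set()
    for _pid, idx_row, rest in _patient_trajectories(log):
        code = str(idx_row["disposition_code"]).strip()
        codes_seen.add(code)
        gp = _gp_first(rest)
        for _, row in rest[rest["service"] == ServiceKind.ED.value].iterrows():
            try:
                avoidable = classify_avoidable(row)
            except ClassificationError:
                n_unclassifiable += 1
                continue
            key = (code, gp)
            den[key] = den.get(key, 0) + 1
            per_code_den[code] = per_code_den.get(code, 0) + 1
            pooled_den += 1
            if avoidable:
                num[key] = num.get(key, 0) + 1
                per_code_num[code] = per_code_num.get(code, 0) + 1
                pooled_num += 1

    pooled = pooled_num / pooled_den if pooled_den else 0.0
    table: dict = {}
    fallbacks = []
    for code in sorted(codes_seen):
        code_pooled = (
            per_code_num.get(code, 0) / per_code_den[code]
            if per_code_den.get(code)
            else pooled
        )
        for gp in (False, True):
            key = (code, gp)
            if den.get(key):
                table[key] = num.get(key, 0) / den[key]
            else:
                table[key] = code_pooled
                fallbacks.append(f"{code}/gp={gp}: pooled over gp strata")
    info = {
        "pooled_proportion": pooled,
        "n_classified": pooled_den,
        "n_avoidable": pooled_num,
        "n_unclassifiable": n_unclassifiable,
        "avoidable_fallbacks": fallbacks,
    }
    return table, info


def collect_delay_samples(log: pd.DataFrame) -> tuple[dict, dict]:
    """Queue samples per (from, to) hop and activity samples per service.

    Queue time for a hop is the gap between leaving the previous contact
    (its end timestamp, or start where no end is recorded) and starting
    the next.  Activity samples require an end timestamp; where the log
    has none the service's sample list is simply absent.
    """
    queue: dict = {}
    activity: dict = {}
    has_end = "end_timestamp" in log.columns
    for _pid, idx_row, rest in _patient_trajectories(log):
        rows = [idx_row] + [row for _, row in rest.iterrows()]
        for prev, nxt in zip(rows[:-1], rows[1:]):
            prev_end = None
            if has_end:
                prev_end = prev["end_timestamp"]
                if prev_end is None or (
                    isinstance(prev_end, float) and math.isnan(prev_end)
                ):
                    prev_end = None
            origin = float(prev_end) if prev_end is not None else float(prev["timestamp"])
            gap = float(nxt["timestamp"]) - origin
            key = (ServiceKind(prev["service"]), ServiceKind(nxt["service"]))
            queue.setdefault(key, []).append(max(gap, 0.0))
        if has_end:
            for row in rows:
                end = row["end_timestamp"]
                if end is None or (isinstance(end, float) and math.isnan(end)):
                    continue
                duration = float(end) - float(row["timestamp"])
                activity.setdefault(ServiceKind(row["service"]), []).append(
                    max(duration, 0.0)
                )
    return queue, activity


def _fit_or_fallback(samples, candidates, n_bins, label, fallbacks) -> FittedDistribution:
    try:
        return fit_distribution(samples, candidates=candidates, n_bins=n_bins)
    except FitError:
        mean = float(np.mean(samples)) if len(samples) else 0.0
        fallbacks.append(f"{label}: {len(samples)} samples; exponential(mean) fallback")
        return FittedDistribution("exponential", (mean,), sse=0.0, n_samples=len(samples))


def estimate_bundle(
    log: pd.DataFrame,
    dispositions: list[DispositionSpec],
    span_minutes: float = float(clock.MINUTES_PER_YEAR),
    start_weekday: int = clock.DEFAULT_START_WEEKDAY,
    candidates=DEFAULT_CANDIDATES,
    n_bins: int = 100,
    max_fit_samples: int = 10000,
    timely_among: str = "pc_first",
) -> ParameterBundle:
    """Assemble a full parameter bundle from an event log.

    ``dispositions`` supplies the timeframe and contact mode per code
    (these are triage-system constants, not log-estimable); weights are
    re-estimated from the log.  Duration samples are capped at
    ``max_fit_samples`` per key (subsampled deterministically) before
    family fitting.
    """
    violations = validate_event_log(log)
    if violations:
        raise EstimationError(
            "event log failed validation:\n  - " + "\n  - ".join(violations[:20])
        )
    timeframes = {d.code: float(d.timeframe_minutes) for d in dispositions}
    weights = estimate_disposition_weights(log)
    unknown = sorted(set(weights) - set(timeframes))
    if unknown:
        raise EstimationError(f"disposition codes without timeframes: {unknown}")

    arrival = estimate_arrival_rates(log, span_minutes, start_weekday)
    transitions, trans_prov = estimate_transitions(log)
    timely = estimate_timely_proportions(log, timeframes, among=timely_among)
    avoidable, avoid_info = estimate_avoidable_proportions(log)
    for d in dispositions:  # complete over codes x {True, False}
        for gp in (False, True):
            avoidable.setdefault((d.code, gp), avoid_info["pooled_proportion"])

    queue_samples, activity_samples = collect_delay_samples(log)
    fit_fallbacks: list[str] = []
    sub_rng = np.random.default_rng(0)  # subsampling only; estimation stays deterministic

    def prepared(samples):
        arr = np.asarray(samples, dtype=float)
        if arr.size > max_fit_samples:
            arr = sub_rng.choice(arr, size=max_fit_samples, replace=False)
        return arr

    queue_delays = {}
    for key, samples in queue_samples.items():
        label = f"queue {key[0].value}->{key[1].value}"
        queue_delays[key] = _fit_or_fallback(
            prepared(samples), candidates, n_bins, label, fit_fallbacks
        )
    activity_delays = {}
    for service, samples in activity_samples.items():
        label = f"activity {service.value}"
        activity_delays[service] = _fit_or_fallback(
            prepared(samples), candidates, n_bins, label, fit_fallbacks
        )
    if not activity_delays:
        fit_fallbacks.append(
            "no end timestamps in log: activity durations default to zero"
        )
        activity_delays = {
            s: FittedDistribution("uniform", (0.0, 0.0))
            for s in ServiceKind
            if s is not ServiceKind.NO_FURTHER_CONTACT
        }

    specs = [
        DispositionSpec(d.code, d.timeframe_minutes, d.contact_mode,
                        weights.get(d.code, 0.0))
        for d in dispositions
    ]
    return ParameterBundle(
        arrival_rates=arrival,
        dispositions=specs,
        timely=timely,
        transitions=transitions,
        queue_delays=queue_delays,
        activity_delays=activity_delays,
        avoidable=avoidable,
        horizon_minutes=span_minutes,
        start_weekday=start_weekday,
        provenance={
            "source": "estimated from event log",
            "n_patients": int(
                (log["service"] == ServiceKind.INDEX_111.value).sum()
            ),
            "timely_among": timely_among,
            "avoidable_info": {
                k: v for k, v in avoid_info.items() if k != "avoidable_fallbacks"
            },
            "fallbacks": (
                trans_prov["transition_fallbacks"]
                + avoid_info["avoidable_fallbacks"]
                + fit_fallbacks
            ),
        },
    )
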
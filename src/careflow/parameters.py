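"""Domain types and the parameter bundle that specifies one model configuration.

A :class:`ParameterBundle` carries everything the engine needs for a run:
stratified arrival rates, triage disposition weights and timeframes, timely
contact proportions, the transition probability tables that drive each
caller's walk through the system, fitted queue/activity duration models and
avoidable ED-attendance proportions.  Bundles live on disk as a directory of
CSV tables plus a small YAML manifest, and every probability-vector
invariant is machine-checked at load time.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import yaml

from . import clock
from .errors import BundleLoadError, BundleValidationError
from .fitting import FittedDistribution


class ServiceKind(str, Enum):
    """Healthcare services a caller can touch within the 72-hour window."""

    INDEX_111 = "INDEX_111"
    PRIMARY_CARE = "PRIMARY_CARE"
    ED = "ED"
    AMBULANCE_999 = "AMBULANCE_999"
    INPATIENT = "INPATIENT"
    SUBSEQUENT_111 = "SUBSEQUENT_111"
    NO_FURTHER_CONTACT = "NO_FURTHER_CONTACT"

    def __str__(self) -> str:  # CSV-friendly
        return self.value


#: Services a transition can leave from (NO_FURTHER_CONTACT is absorbing).
TRANSITION_SOURCES = tuple(
    s for s in ServiceKind if s is not ServiceKind.NO_FURTHER_CONTACT
)
#: Services a transition can arrive at (the index call is never re-entered).
TRANSITION_DESTS = tuple(s for s in ServiceKind if s is not ServiceKind.INDEX_111)

QUARTERS = (1, 2, 3, 4)

CONTACT_MODES = ("face_to_face", "remote")

#: 72-hour per-patient cap, minutes.
DEFAULT_PATIENT_CAP = 4320.0
#: One simulated year, minutes.
DEFAULT_HORIZON = float(clock.MINUTES_PER_YEAR)

_PROB_TOL = 1e-9


@dataclass(frozen=True)
class DispositionSpec:
    """A primary-care triage outcome: contact timeframe, mode and sampling weight."""

    code: str
    timeframe_minutes: int
    contact_mode: str
    weight: float


@dataclass
class ParameterBundle:
    """Complete model specification consumed by the simulation engine.

    Attributes
    ----------
    arrival_rates
        Mean inter-arrival minutes per (hour, quarter, is_weekend) stratum;
        ``+inf`` encodes a stratum with no arrivals.
    dispositions
        Primary-care disposition specs; weights need not be normalised.
    timely
        Probability of a timely primary-care contact per disposition code.
    transitions
        ``(source service, gp_first_contact, quarter) -> {destination: p}``.
    queue_delays
        Fitted wait-time model per (from service, to service).
    activity_delays
        Fitted contact-duration model per service.
    avoidable
        Avoidable-ED probability per (disposition code, gp_first_contact).
    """

    arrival_rates: dict[tuple, float]
    dispositions: list[DispositionSpec]
    timely: dict[str, float]
    transitions: dict[tuple, dict[ServiceKind, float]]
    queue_delays: dict[tuple, FittedDistribution]
    activity_delays: dict[ServiceKind, FittedDistribution]
    avoidable: dict[tuple, float]
    horizon_minutes: float = DEFAULT_HORIZON
    patient_cap_minutes: float = DEFAULT_PATIENT_CAP
    start_weekday: int = clock.DEFAULT_START_WEEKDAY
    provenance: dict = field(default_factory=dict)

    def disposition_codes(self) -> list[str]:
        return [d.code for d in self.dispositions]

    def copy(self) -> "ParameterBundle":
        return ParameterBundle(
            arrival_rates=dict(self.arrival_rates),
            dispositions=list(self.dispositions),
            timely=dict(self.timely),
            transitions={k: dict(v) for k, v in self.transitions.items()},
            queue_delays=dict(self.queue_delays),
            activity_delays=dict(self.activity_delays),
            avoidable=dict(self.avoidable),
            horizon_minutes=self.horizon_minutes,
            patient_cap_minutes=self.patient_cap_minutes,
            start_weekday=self.start_weekday,
            provenance=dict(self.provenance),
        )


def validate_bundle(bundle: ParameterBundle) -> list[str]:
    """Check every structural invariant; return human-readable violations.

    Total on structurally complete input: violations are returned, never
    raised.  An empty list means the bundle is fit for simulation.
    """
    v: list[str] = []

    # --- arrivals: all 192 strata, positive (or +inf) means
    expected = set(clock.all_strata())
    supplied = set(bundle.arrival_rates)
    for stratum in sorted(expected - supplied, key=str):
        v.append(f"arrivals: missing stratum (hour={stratum[0]}, quarter={stratum[1]}, is_weekend={stratum[2]})")
    for stratum in sorted(supplied - expected, key=str):
        v.append(f"arrivals: unknown stratum key {stratum!r}")
    for stratum in sorted(supplied & expected, key=str):
        mean = bundle.arrival_rates[stratum]
        if not (mean > 0):  # rejects 0, negatives and NaN; +inf passes
            v.append(f"arrivals: stratum {stratum} mean inter-arrival must be > 0, got {mean}")

    # --- dispositions
    if not bundle.dispositions:
        v.append("dispositions: table is empty")
    codes = bundle.disposition_codes()
    for code in sorted({c for c in codes if codes.count(c) > 1}):
        v.append(f"dispositions: duplicate code {code!r}")
    for d in bundle.dispositions:
        if not (0 < d.timeframe_minutes <= DEFAULT_PATIENT_CAP):
            v.append(f"dispositions: {d.code} timeframe_minutes must be in (0, {int(DEFAULT_PATIENT_CAP)}], got {d.timeframe_minutes}")
        if d.contact_mode not in CONTACT_MODES:
            v.append(f"dispositions: {d.code} contact_mode must be one of {CONTACT_MODES}, got {d.contact_mode!r}")
        if not (d.weight >= 0):
            v.append(f"dispositions: {d.code} weight must be >= 0, got {d.weight}")
    total_weight = sum(d.weight for d in bundle.dispositions)
    if bundle.dispositions and not (total_weight > 0):
        v.append(f"dispositions: weights must sum to a positive value, got {total_weight}")

    # --- timely table
    for code in codes:
        if code not in bundle.timely:
            v.append(f"timely: missing disposition code {code!r}")
    for code, p in sorted(bundle.timely.items()):
        if not (0 <= p <= 1):
            v.append(f"timely: p_timely[{code!r}] must be in [0,1], got {p}")

    # --- transition table
    expected_keys = {
        (src, gp, q)
        for src in TRANSITION_SOURCES
        for gp in (False, True)
        for q in QUARTERS
    }
    for key in sorted(expected_keys - set(bundle.transitions), key=str):
        v.append(f"transitions: missing row (from={key[0]}, gp_first_contact={key[1]}, quarter={key[2]})")
    for key, row in sorted(bundle.transitions.items(), key=lambda kv: str(kv[0])):
        src, gp, q = key
        if key not in expected_keys:
            v.append(f"transitions: unknown row key {key!r}")
            continue
        total = 0.0
        for dest, p in row.items():
            if dest is ServiceKind.INDEX_111 and p != 0:
                v.append(f"transitions: row {key} assigns mass {p} to INDEX_111")
            if not (p >= 0):
                v.append(f"transitions: row {key} probability for {dest} must be >= 0, got {p}")
            total += p
        if abs(total - 1.0) > _PROB_TOL:
            v.append(f"transitions: row (from={src}, gp_first_contact={gp}, quarter={q}) sums to {total!r}, not 1")

    # --- avoidable table
    for code in codes:
        for gp in (False, True):
            if (code, gp) not in bundle.avoidable:
                v.append(f"avoidable: missing entry (code={code!r}, gp_first_contact={gp})")
    for (code, gp), p in sorted(bundle.avoidable.items()):
        if not (0 <= p <= 1):
            v.append(f"avoidable: p_avoidable[({code!r}, {gp})] must be in [0,1], got {p}")

    # --- delay models: every reachable hop must be sampleable
    for key, dist in sorted(bundle.queue_delays.items(), key=lambda kv: str(kv[0])):
        msg = dist.validate()
        if msg:
            v.append(f"delays_queue: {key[0]}->{key[1]}: {msg}")
    for service, dist in sorted(bundle.activity_delays.items(), key=lambda kv: str(kv[0])):
        msg = dist.validate()
        if msg:
            v.append(f"delays_activity: {service}: {msg}")
    for key, row in bundle.transitions.items():
        if key not in {(s, g, q) for s in TRANSITION_SOURCES for g in (False, True) for q in QUARTERS}:
            continue
        src = key[0]
        for dest, p in row.items():
            if p > 0 and dest not in (ServiceKind.NO_FURTHER_CONTACT, ServiceKind.INDEX_111):
                if (src, dest) not in bundle.queue_delays:
                    v.append(f"delays_queue: missing distribution for reachable hop {src}->{dest}")
                if dest not in bundle.activity_delays:
                    v.append(f"delays_activity: missing distribution for reachable service {dest}")

    # --- scalars
    if not (bundle.horizon_minutes > 0):
        v.append(f"horizon_minutes must be > 0, got {bundle.horizon_minutes}")
    if not (bundle.patient_cap_minutes > 0):
        v.append(f"patient_cap_minutes must be > 0, got {bundle.patient_cap_minutes}")
    if not (0 <= bundle.start_weekday <= 6):
        v.append(f"start_weekday must be in 0..6, got {bundle.start_weekday}")

    # de-duplicate while keeping order
    seen: set[str] = set()
    return [x for x in v if not (x in seen or seen.add(x))]


# ---------------------------------------------------------------------------
# Bundle directory I/O
#
# Layout: <dir>/manifest.yaml plus the CSV tables it names.  Floats are
# written with repr() so a write/read round trip is exact.

_MANIFEST = "manifest.yaml"
_FILES = {
    "arrivals": "arrivals.csv",
    "dispositions": "dispositions.csv",
    "timely": "timely.csv",
    "transitions": "transitions.csv",
    "delays_queue": "delays_queue.csv",
    "delays_activity": "delays_activity.csv",
    "avoidable": "avoidable.csv",
}


def _fmt_float(x: float) -> str:
    return repr(float(x))


def _fmt_bool(b: bool) -> str:
    return "true" if b else "false"


def _parse_bool(s: str, where: str) -> bool:
    t = s.strip().lower()
    if t == "true":
        return True
    if t == "false":
        return False
    raise BundleLoadError(f"{where}: expected true/false, got {s!r}")


def _parse_float(s: str, where: str) -> float:
    try:
        return float(s)
    except ValueError:
        raise BundleLoadError(f"{where}: expected a number, got {s!r}") from None


def _parse_service(s: str, where: str) -> ServiceKind:
    try:
        return ServiceKind(s.strip())
    except ValueError:
        raise BundleLoadError(
            f"{where}: unknown service code {s!r} (expected one of "
            f"{[k.value for k in ServiceKind]})"
        ) from None


def _dist_row(prefix: dict, dist: FittedDistribution) -> dict:
    row = dict(prefix)
    row["family"] = dist.family
    for i in range(2):
        row[f"param{i + 1}"] = (
            _fmt_float(dist.params[i]) if i < len(dist.params) else ""
        )
    row["sse"] = _fmt_float(dist.sse)
    row["n_samples"] = str(dist.n_samples)
    return row


def _dist_from_row(row: dict, where: str) -> FittedDistribution:
    family = row["family"].strip()
    params = []
    for key in ("param1", "param2"):
        raw = row.get(key, "")
        if raw is not None and raw.strip() != "":
            params.append(_parse_float(raw, where))
    dist = FittedDistribution(
        family,
        tuple(params),
        sse=_parse_float(row.get("sse", "0") or "0", where),
        n_samples=int(row.get("n_samples", "0") or 0),
    )
    msg = dist.validate()
    if msg:
        raise BundleLoadError(f"{where}: {msg}")
    return dist


def _write_csv(path: Path, header: list[str], rows: list[dict]) -> None:
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=header)
        writer.writeheader()
        writer.writerows(rows)


def _read_csv(path: Path) -> list[dict]:
    if not path.exists():
        raise BundleLoadError(f"missing bundle table: {path}")
    with path.open(newline="", encoding="utf-8") as fh:
        return list(csv.DictReader(fh))


def write_bundle(bundle: ParameterBundle, path) -> None:
    """Write a bundle as a directory of CSV tables plus a YAML manifest."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)

    _write_csv(
        root / _FILES["arrivals"],
        ["hour", "quarter", "is_weekend", "mean_interarrival_min"],
        [
            {
                "hour": str(h),
                "quarter": str(q),
                "is_weekend": _fmt_bool(w),
                "mean_interarrival_min": _fmt_float(m),
            }
            for (h, q, w), m in sorted(bundle.arrival_rates.items(), key=str)
        ],
    )
    _write_csv(
        root / _FILES["dispositions"],
        ["code", "timeframe_min", "contact_mode", "weight"],
        [
            {
                "code": d.code,
                "timeframe_min": str(d.timeframe_minutes),
                "contact_mode": d.contact_mode,
                "weight": _fmt_float(d.weight),
            }
            for d in bundle.dispositions
        ],
    )
    _write_csv(
        root / _FILES["timely"],
        ["code", "p_timely"],
        [
            {"code": c, "p_timely": _fmt_float(p)}
            for c, p in sorted(bundle.timely.items())
        ],
    )
    _write_csv(
        root / _FILES["transitions"],
        ["from", "gp_first_contact", "quarter", "to", "probability"],
        [
            {
                "from": src.value,
                "gp_first_contact": _fmt_bool(gp),
                "quarter": str(q),
                "to": dest.value,
                "probability": _fmt_float(p),
            }
            for (src, gp, q), row in sorted(
                bundle.transitions.items(), key=lambda kv: str(kv[0])
            )
            for dest, p in sorted(row.items(), key=lambda kv: kv[0].value)
        ],
    )
    _write_csv(
        root / _FILES["delays_queue"],
        ["from", "to", "family", "param1", "param2", "sse", "n_samples"],
        [
            _dist_row({"from": src.value, "to": dest.value}, dist)
            for (src, dest), dist in sorted(
                bundle.queue_delays.items(), key=lambda kv: str(kv[0])
            )
        ],
    )
    _write_csv(
        root / _FILES["delays_activity"],
        ["service", "family", "param1", "param2", "sse", "n_samples"],
        [
            _dist_row({"service": s.value}, dist)
            for s, dist in sorted(
                bundle.activity_delays.items(), key=lambda kv: str(kv[0])
            )
        ],
    )
    _write_csv(
        root / _FILES["avoidable"],
        ["code", "gp_first_contact", "p_avoidable"],
        [
            {
                "code": code,
                "gp_first_contact": _fmt_bool(gp),
                "p_avoidable": _fmt_float(p),
            }
            for (code, gp), p in sorted(bundle.avoidable.items())
        ],
    )

    manifest = {
        "horizon_minutes": float(bundle.horizon_minutes),
        "patient_cap_minutes": float(bundle.patient_cap_minutes),
        "start_weekday": clock.WEEKDAY_NAMES[bundle.start_weekday],
        "files": dict(_FILES),
        "provenance": bundle.provenance,
    }
    with (root / _MANIFEST).open("w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def read_bundle(path) -> ParameterBundle:
    """Read and validate a bundle directory; raise on any violation."""
    root = Path(path)
    manifest_path = root / _MANIFEST
    if not manifest_path.exists():
        raise BundleLoadError(f"missing bundle manifest: {manifest_path}")
    with manifest_path.open(encoding="utf-8") as fh:
        manifest = yaml.safe_load(fh) or {}
    files = manifest.get("files", {})
    for table in _FILES:
        if table not in files:
            raise BundleLoadError(f"manifest omits required table {table!r}")

    def table(name: str) -> tuple[Path, list[dict]]:
        p = root / files[name]
        return p, _read_csv(p)

    path_a, rows = table("arrivals")
    arrivals: dict[tuple, float] = {}
    for i, row in enumerate(rows, start=2):
        where = f"{path_a}:{i}"
        key = (
            int(row["hour"]),
            int(row["quarter"]),
            _parse_bool(row["is_weekend"], where),
        )
        arrivals[key] = _parse_float(row["mean_interarrival_min"], where)

    path_d, rows = table("dispositions")
    dispositions = []
    for i, row in enumerate(rows, start=2):
        where = f"{path_d}:{i}"
        try:
            dispositions.append(
                DispositionSpec(
                    code=row["code"].strip(),
                    timeframe_minutes=int(row["timeframe_min"]),
                    contact_mode=row["contact_mode"].strip(),
                    weight=_parse_float(row["weight"], where),
                )
            )
        except (KeyError, ValueError) as exc:
            raise BundleLoadError(f"{where}: malformed disposition row ({exc})") from None

    path_t, rows = table("timely")
    timely = {}
    for i, row in enumerate(rows, start=2):
        timely[row["code"].strip()] = _parse_float(row["p_timely"], f"{path_t}:{i}")

    path_tr, rows = table("transitions")
    transitions: dict[tuple, dict[ServiceKind, float]] = {}
    for i, row in enumerate(rows, start=2):
        where = f"{path_tr}:{i}"
        key = (
            _parse_service(row["from"], where),
            _parse_bool(row["gp_first_contact"], where),
            int(row["quarter"]),
        )
        dest = _parse_service(row["to"], where)
        transitions.setdefault(key, {})[dest] = _parse_float(row["probability"], where)

    path_q, rows = table("delays_queue")
    queue_delays = {}
    for i, row in enumerate(rows, start=2):
        where = f"{path_q}:{i}"
        key = (_parse_service(row["from"], where), _parse_service(row["to"], where))
        queue_delays[key] = _dist_from_row(row, where)

    path_ac, rows = table("delays_activity")
    activity_delays = {}
    for i, row in enumerate(rows, start=2):
        where = f"{path_ac}:{i}"
        activity_delays[_parse_service(row["service"], where)] = _dist_from_row(row, where)

    path_av, rows = table("avoidable")
    avoidable = {}
    for i, row in enumerate(rows, start=2):
        where = f"{path_av}:{i}"
        key = (row["code"].strip(), _parse_bool(row["gp_first_contact"], where))
        avoidable[key] = _parse_float(row["p_avoidable"], where)

    bundle = ParameterBundle(
        arrival_rates=arrivals,
        dispositions=dispositions,
        timely=timely,
        transitions=transitions,
        queue_delays=queue_delays,
        activity_delays=activity_delays,
        avoidable=avoidable,
        horizon_minutes=float(manifest.get("horizon_minutes", DEFAULT_HORIZON)),
        patient_cap_minutes=float(
            manifest.get("patient_cap_minutes", DEFAULT_PATIENT_CAP)
        ),
        start_weekday=clock.parse_weekday(
            manifest.get("start_weekday", clock.DEFAULT_START_WEEKDAY)
        ),
        provenance=manifest.get("provenance", {}) or {},
    )
    violations = validate_bundle(bundle)
    if violations:
        raise BundleValidationError(violations)
    return bundle
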
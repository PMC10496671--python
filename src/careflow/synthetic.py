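"""Synthetic ground truth and synthetic linked event logs.

The study population this package models — callers to an urgent-care
triage line handed a primary-care disposition, tracked for 72 hours
across linked 111/999/primary-care/ED/in-patient records — lives in a
restricted research database with no public release.  This module
therefore builds (a) a fully specified, *invented* ground-truth
parameter bundle whose magnitudes are realistic for a one-year regional
extract (about 56 000 index calls a year, roughly 48% of callers making
primary care their first contact and 39% no further contact, avoidable
ED proportions near 0.11), and (b) synthetic event logs simulated from
that truth and re-labelled into the estimation input schema.  Estimators
can then be tested by parameter recovery without any data access.

All values here are synthetic fixtures; none are measured quantities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import clock
from .engine import run_simulation
from .errors import BundleValidationError
from .estimation import EVENT_LOG_CSV_COLUMNS
from .fitting import FittedDistribution
from .parameters import (
    DispositionSpec,
    ParameterBundle,
    ServiceKind,
    validate_bundle,
)
from .scenarios import BASE_SCENARIO

#: Yearly index-call volume the default truth is scaled to.
DEFAULT_YEARLY_CALLS = 56_000.0

# Hour-of-day arrival intensity shape (unit mean is irrelevant; the table
# is rescaled to the yearly volume).  Two humps: morning and early evening,
# with a quiet small-hours trough.
_HOURLY_SHAPE = np.array(
    [
        0.60, 0.50, 0.40, 0.35, 0.35, 0.40,  # 00-05
        0.50, 0.70, 1.20, 1.50, 1.40, 1.30,  # 06-11
        1.10, 1.00, 0.90, 0.90, 1.00, 1.30,  # 12-17
        1.50, 1.40, 1.20, 1.00, 0.80, 0.70,  # 18-23
    ]
)
#: Weekend days carry heavier per-hour volume (out-of-hours demand).
_WEEKEND_MULT = 1.8
_QUARTER_MULT = {1: 1.10, 2: 0.95, 3: 0.92, 4: 1.03}

_DISPOSITIONS = [
    # (code, timeframe min, contact mode, weight, p_timely)
    ("PC_REMOTE_1H", 60, "remote", 0.12, 0.55),
    ("PC_F2F_2H", 120, "face_to_face", 0.18, 0.50),
    ("PC_F2F_6H", 360, "face_to_face", 0.30, 0.60),
    ("PC_REMOTE_12H", 720, "remote", 0.22, 0.65),
    ("PC_F2F_24H", 1440, "face_to_face", 0.18, 0.70),
]

S = ServiceKind
# Base next-service rows.  The INDEX_111 row is the marginal first-contact
# distribution (identical under both gp strata); for the rest, callers who
# reached primary care first (gp=True) are lighter users of ED/999/111.
_BASE_TRANSITIONS = {
    (S.INDEX_111, False): {
        S.PRIMARY_CARE: 0.476, S.NO_FURTHER_CONTACT: 0.388, S.ED: 0.100,
        S.AMBULANCE_999: 0.016, S.SUBSEQUENT_111: 0.015, S.INPATIENT: 0.005,
    },
    (S.PRIMARY_CARE, True): {
        S.NO_FURTHER_CONTACT: 0.62, S.PRIMARY_CARE: 0.25, S.ED: 0.06,
        S.SUBSEQUENT_111: 0.04, S.AMBULANCE_999: 0.01, S.INPATIENT: 0.02,
    },
    (S.PRIMARY_CARE, False): {
        S.NO_FURTHER_CONTACT: 0.55, S.PRIMARY_CARE: 0.20, S.ED: 0.12,
        S.SUBSEQUENT_111: 0.07, S.AMBULANCE_999: 0.03, S.INPATIENT: 0.03,
    },
    (S.ED, True): {
        S.NO_FURTHER_CONTACT: 0.60, S.INPATIENT: 0.25, S.PRIMARY_CARE: 0.08,
        S.ED: 0.03, S.SUBSEQUENT_111: 0.03, S.AMBULANCE_999: 0.01,
    },
    (S.ED, False): {
        S.NO_FURTHER_CONTACT: 0.55, S.INPATIENT: 0.28, S.PRIMARY_CARE: 0.07,
        S.ED: 0.04, S.SUBSEQUENT_111: 0.04, S.AMBULANCE_999: 0.02,
    },
    (S.AMBULANCE_999, True): {
        S.ED: 0.55, S.NO_FURTHER_CONTACT: 0.30, S.PRIMARY_CARE: 0.08,
        S.SUBSEQUENT_111: 0.04, S.INPATIENT: 0.02, S.AMBULANCE_999: 0.01,
    },
    (S.AMBULANCE_999, False): {
        S.ED: 0.60, S.NO_FURTHER_CONTACT: 0.25, S.PRIMARY_CARE: 0.06,
        S.SUBSEQUENT_111: 0.05, S.INPATIENT: 0.03, S.AMBULANCE_999: 0.01,
    },
    (S.INPATIENT, True): {
        S.NO_FURTHER_CONTACT: 0.80, S.PRIMARY_CARE: 0.12, S.ED: 0.03,
        S.SUBSEQUENT_111: 0.03, S.INPATIENT: 0.01, S.AMBULANCE_999: 0.01,
    },
    (S.INPATIENT, False): {
        S.NO_FURTHER_CONTACT: 0.78, S.PRIMARY_CARE: 0.10, S.ED: 0.05,
        S.SUBSEQUENT_111: 0.04, S.INPATIENT: 0.02, S.AMBULANCE_999: 0.01,
    },
    (S.SUBSEQUENT_111, True): {
        S.NO_FURTHER_CONTACT: 0.40, S.PRIMARY_CARE: 0.30, S.ED: 0.12,
        S.AMBULANCE_999: 0.08, S.SUBSEQUENT_111: 0.08, S.INPATIENT: 0.02,
    },
    (S.SUBSEQUENT_111, False): {
        S.NO_FURTHER_CONTACT: 0.35, S.PRIMARY_CARE: 0.25, S.ED: 0.18,
        S.AMBULANCE_999: 0.12, S.SUBSEQUENT_111: 0.08, S.INPATIENT: 0.02,
    },
}

#: Mean queue (wait) minutes by destination service.
_QUEUE_MEANS = {
    S.PRIMARY_CARE: 240.0,
    S.ED: 120.0,
    S.AMBULANCE_999: 30.0,
    S.INPATIENT: 90.0,
    S.SUBSEQUENT_111: 180.0,
}
_QUEUE_SIGMA = 0.6  # lognormal shape for all queue models

_ACTIVITY = {
    S.INDEX_111: FittedDistribution("uniform", (5.0, 10.0)),  # 5-15 min call
    S.PRIMARY_CARE: FittedDistribution("gamma", (2.0, 7.5)),  # mean 15 min
    S.ED: FittedDistribution("lognormal", (0.5, 158.8)),  # mean ~180 min
    S.AMBULANCE_999: FittedDistribution("gamma", (3.0, 15.0)),  # mean 45 min
    S.INPATIENT: FittedDistribution("lognormal", (0.5, 1270.4)),  # mean ~1440 min
    S.SUBSEQUENT_111: FittedDistribution("uniform", (5.0, 10.0)),
}

#: Per-code avoidable-ED base probabilities (pooled value near 0.11).
_AVOIDABLE_BASE = {
    "PC_REMOTE_1H": 0.09,
    "PC_F2F_2H": 0.10,
    "PC_F2F_6H": 0.11,
    "PC_REMOTE_12H": 0.12,
    "PC_F2F_24H": 0.13,
}
_AVOIDABLE_GP_SHIFT = 0.005  # gp-first callers marginally more avoidable


@dataclass
class GroundTruthScenario:
    """A known-truth bundle plus the settings used to synthesise a log."""

    bundle: ParameterBundle
    seed: int
    yearly_calls: float = DEFAULT_YEARLY_CALLS
    drop_end_timestamps: bool = False


def _arrival_table(yearly_calls: float, start_weekday: int) -> dict:
    """Stratified mean inter-arrival minutes scaled so the closed-form
    expected yearly volume equals ``yearly_calls``."""
    exposure = clock.stratum_exposure_minutes(
        float(clock.MINUTES_PER_YEAR), start_weekday
    )
    raw = {}
    for (hour, quarter, weekend) in exposure:
        intensity = _HOURLY_SHAPE[hour] * _QUARTER_MULT[quarter]
        if weekend:
            intensity *= _WEEKEND_MULT
        raw[(hour, quarter, weekend)] = intensity
    total = sum(exposure[s] * raw[s] for s in raw)
    scale = yearly_calls / total  # calls per minute per unit intensity
    return {s: 1.0 / (raw[s] * scale) for s in raw}


def _transition_table() -> dict:
    """Quarterised transition rows with a small seasonal tilt.

    Per quarter a little probability mass moves between primary care and
    no-further-contact so quarters are genuinely distinct but rows still
    sum to one exactly.
    """
    tilt = {1: 0.01, 2: 0.0, 3: -0.01, 4: 0.0}
    base = dict(_BASE_TRANSITIONS)
    # the marginal first-contact row is identical under both gp strata
    base[(S.INDEX_111, True)] = dict(base[(S.INDEX_111, False)])
    table = {}
    for (src, gp), row in base.items():
        for quarter in (1, 2, 3, 4):
            shifted = dict(row)
            d = tilt[quarter]
            shifted[S.PRIMARY_CARE] = round(shifted[S.PRIMARY_CARE] + d, 12)
            shifted[S.NO_FURTHER_CONTACT] = round(
                shifted[S.NO_FURTHER_CONTACT] - d, 12
            )
            table[(src, gp, quarter)] = shifted
    return table


def _queue_table() -> dict:
    """Lognormal queue model for every (source, destination) hop."""
    sources = [s for s in ServiceKind if s is not S.NO_FURTHER_CONTACT]
    out = {}
    for src in sources:
        for dest, mean in _QUEUE_MEANS.items():
            scale = mean / float(np.exp(_QUEUE_SIGMA**2 / 2.0))
            out[(src, dest)] = FittedDistribution(
                "lognormal", (_QUEUE_SIGMA, scale)
            )
    return out


def make_default_truth(seed: int = 0) -> GroundTruthScenario:
    """The package's reference ground-truth scenario.

    Every value is an invented but realistic fixture (documented in the
    module docstring); the bundle passes validation by construction.
    """
    start_weekday = clock.DEFAULT_START_WEEKDAY
    dispositions = [
        DispositionSpec(code, tf, mode, weight)
        for code, tf, mode, weight, _pt in _DISPOSITIONS
    ]
    timely = {code: pt for code, _tf, _m, _w, pt in _DISPOSITIONS}
    avoidable = {}
    for code, base in _AVOIDABLE_BASE.items():
        avoidable[(code, True)] = base + _AVOIDABLE_GP_SHIFT
        avoidable[(code, False)] = base - _AVOIDABLE_GP_SHIFT
    bundle = ParameterBundle(
        arrival_rates=_arrival_table(DEFAULT_YEARLY_CALLS, start_weekday),
        dispositions=dispositions,
        timely=timely,
        transitions=_transition_table(),
        queue_delays=_queue_table(),
        activity_delays=dict(_ACTIVITY),
        avoidable=avoidable,
        start_weekday=start_weekday,
        provenance={"source": "synthetic ground truth (invented fixture)", "seed": seed},
    )
    violations = validate_bundle(bundle)
    if violations:  # construction bug guard, not a user-facing path
        raise BundleValidationError(violations)
    return GroundTruthScenario(bundle=bundle, seed=seed)


def expected_yearly_arrivals(bundle: ParameterBundle) -> float:
    """Closed-form expected index calls over one year: sum of
    stratum exposure / stratum mean inter-arrival."""
    exposure = clock.stratum_exposure_minutes(
        float(clock.MINUTES_PER_YEAR), bundle.start_weekday
    )
    return float(
        sum(
            exposure[s] / m
            for s, m in bundle.arrival_rates.items()
            if np.isfinite(m)
        )
    )


# Non-empty subsets of the three type-1 resource flags, used to label
# non-avoidable ED attendances consistently with the classifier.
_NONAVOIDABLE_MASKS = [
    (True, False, False), (False, True, False), (False, False, True),
    (True, True, False), (True, False, True), (False, True, True),
    (True, True, True),
]


def generate_log(truth: GroundTruthScenario) -> pd.DataFrame:
    """Simulate one year under the truth bundle and emit an estimation-
    schema event log.

    ED resource flags are reverse-engineered from each attendance's
    sampled avoidable label (avoidable -> no resources used; otherwise a
    uniformly chosen non-empty subset), so ``classify_avoidable``
    reproduces the simulated labels exactly.  All EDs are type 1.
    """
    log, _summary = run_simulation(truth.bundle, BASE_SCENARIO, seed=truth.seed)
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 0xED]))

    out = pd.DataFrame(
        {
            "patient_id": log["patient_id"],
            "timestamp": log["timestamp"],
            "service": log["service"],
            "disposition_code": log["disposition_code"],
            "ed_investigations": "",
            "ed_treatments": "",
            "ed_referral": "",
            "is_type1_ed": "",
            "end_timestamp": "" if truth.drop_end_timestamps else log["end_timestamp"],
        }
    )
    is_ed = (log["service"] == S.ED.value).to_numpy()
    avoidable = (log["avoidable"] == "true").to_numpy()
    inv = np.empty(len(log), dtype=object)
    trt = np.empty(len(log), dtype=object)
    ref = np.empty(len(log), dtype=object)
    inv[:] = trt[:] = ref[:] = ""
    t1 = np.where(is_ed, "true", "")
    for i in np.flatnonzero(is_ed):
        if avoidable[i]:
            inv[i] = trt[i] = ref[i] = "false"
        else:
            mask = _NONAVOIDABLE_MASKS[int(rng.integers(len(_NONAVOIDABLE_MASKS)))]
            inv[i], trt[i], ref[i] = (
                "true" if m else "false" for m in mask
            )
    out["ed_investigations"] = inv
    out["ed_treatments"] = trt
    out["ed_referral"] = ref
    out["is_type1_ed"] = t1
    return out[EVENT_LOG_CSV_COLUMNS]


def write_log(log: pd.DataFrame, path) -> None:
    log.to_csv(path, index=False, float_format="%.6f")
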
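"""Replicated runs, 95% confidence intervals and scenario comparison.

The model is stochastic, so each scenario is replicated (default 100
one-year runs) and every count is reported as a mean with a normal-
approximation 95% CI (mean +/- 1.96 * sd / sqrt(n)).  Base and what-if
replication sets are compared run-by-run (runs paired by index, which is
the variance-reducing choice under deterministic seed derivation): the
mean difference is what-if minus base, and the mean percentage change is
on the ratio scale, 100 * what-if / base, so 100 means no change and 196
means near-doubling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import clock
from .engine import RunSummary, run_simulation
from .parameters import ParameterBundle, ServiceKind
from .scenarios import BASE_SCENARIO, ScenarioFlags

Z_95 = 1.96

#: Services reported in the base vs what-if comparison, with display labels.
REPORT_SERVICES = [
    (ServiceKind.AMBULANCE_999, "Ambulance service"),
    (ServiceKind.ED, "Emergency department"),
    (ServiceKind.PRIMARY_CARE, "Primary care"),
    (ServiceKind.INPATIENT, "In-patient"),
    (ServiceKind.SUBSEQUENT_111, "111"),
]


def proportion_pct(numerator: float, denominator: float) -> float:
    """A proportion on the percentage scale, e.g. 1029/9290 -> 11.08."""
    if denominator == 0:
        return float("nan")
    return 100.0 * numerator / denominator


def percentage_ratio(base: float, whatif: float) -> float:
    """Percentage-change on the ratio scale: 100 means no change."""
    if base == 0:
        return float("nan")
    return 100.0 * whatif / base


def mean_ci(values) -> tuple[float, float, float]:
    """(mean, lower, upper) with a normal-approximation 95% CI.

    The CI half-width is 1.96 * sd / sqrt(n) with the sample sd (ddof=1);
    identical values give a zero-width interval.
    """
    arr = np.asarray(values, dtype=float)
    m = float(np.mean(arr))
    if arr.size < 2:
        return m, m, m
    half = Z_95 * float(np.std(arr, ddof=1)) / np.sqrt(arr.size)
    return m, m - half, m + half


def derive_run_seeds(master_seed: int, n_runs: int) -> list[int]:
    """Distinct, deterministic per-run seeds below 2**31."""
    seeds: list[int] = []
    seen: set[int] = set()
    counter = 0
    while len(seeds) < n_runs:
        s = int(
            np.random.SeedSequence([master_seed, counter]).generate_state(1)[0]
            % (2**31)
        )
        counter += 1
        if s not in seen:
            seen.add(s)
            seeds.append(s)
    return seeds


@dataclass
class ReplicationSet:
    """N independent runs of one scenario under a single master seed."""

    label: str
    master_seed: int
    summaries: list[RunSummary]
    seeds: list[int] = field(default_factory=list)

    @property
    def n_runs(self) -> int:
        return len(self.summaries)

    def totals(self, service: ServiceKind) -> np.ndarray:
        return np.array([s.totals.get(service, 0) for s in self.summaries], float)

    def quarter_counts(self, service: ServiceKind, quarter: int) -> np.ndarray:
        return np.array(
            [s.counts.get((service, quarter), 0) for s in self.summaries], float
        )

    def avoidable_counts(self) -> np.ndarray:
        return np.array([s.avoidable_ed for s in self.summaries], float)

    def avoidable_proportions_pct(self) -> np.ndarray:
        return np.array(
            [proportion_pct(s.avoidable_ed, s.ed_attendances) for s in self.summaries]
        )

    def first_contact_pct(self, service: ServiceKind) -> np.ndarray:
        return np.array(
            [
                proportion_pct(s.first_contact.get(service, 0), s.n_patients)
                for s in self.summaries
            ]
        )

    def n_patients(self) -> np.ndarray:
        return np.array([s.n_patients for s in self.summaries], float)


def replicate(
    bundle: ParameterBundle,
    flags: ScenarioFlags = BASE_SCENARIO,
    n_runs: int = 100,
    master_seed: int = 0,
) -> ReplicationSet:
    """Run the scenario ``n_runs`` times with derived, distinct seeds."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    seeds = derive_run_seeds(master_seed, n_runs)
    summaries = []
    for i, seed in enumerate(seeds):
        _log, summary = run_simulation(
            bundle, flags, seed=seed, run_id=f"{flags.label}-{i:03d}"
        )
        summaries.append(summary)
    return ReplicationSet(
        label=flags.label, master_seed=master_seed, summaries=summaries, seeds=seeds
    )


def summarize(repset: ReplicationSet) -> pd.DataFrame:
    """Mean and 95% CI for every aggregate a run reports.

    One row per metric: per-service totals and quarterly counts, the
    avoidable-ED count and proportion, first-contact percentages and the
    yearly caller volume.
    """
    rows = []

    def add(metric: str, values):
        m, lo, hi = mean_ci(values)
        rows.append({"metric": metric, "mean": m, "ci_lower": lo, "ci_upper": hi})

    add("n_patients", repset.n_patients())
    for service, label in REPORT_SERVICES:
        add(f"total:{label}", repset.totals(service))
        for quarter in (1, 2, 3, 4):
            add(f"quarterly:{label}:Q{quarter}", repset.quarter_counts(service, quarter))
    add("avoidable_ed:count", repset.avoidable_counts())
    add("avoidable_ed:pct", repset.avoidable_proportions_pct())
    for service in [s for s in ServiceKind if s is not ServiceKind.INDEX_111]:
        add(f"first_contact_pct:{service.value}", repset.first_contact_pct(service))
    return pd.DataFrame(rows, columns=["metric", "mean", "ci_lower", "ci_upper"])


@dataclass
class ComparisonReport:
    """Paired base vs what-if statistics in the shape of the results table."""

    services: pd.DataFrame
    avoidable: pd.DataFrame
    first_contact: pd.DataFrame
    metadata: dict

    def to_csv(self, path) -> None:
        self.services.to_csv(path, index=False, float_format="%.4f")


def compare(base: ReplicationSet, whatif: ReplicationSet) -> ComparisonReport:
    """Pair runs by index and report means, CIs, differences and % change.

    Percentage change is the ratio scale (100 = no change).  If any base
    run has a zero count for a service, the percentage change for that
    service is reported as NaN with a warning.
    """
    if base.n_runs != whatif.n_runs:
        raise ValueError(
            f"replication sets differ in size ({base.n_runs} vs {whatif.n_runs})"
        )
    service_rows = []
    for service, label in REPORT_SERVICES:
        b = base.totals(service)
        w = whatif.totals(service)
        bm, blo, bhi = mean_ci(b)
        wm, wlo, whi = mean_ci(w)
        dm, dlo, dhi = mean_ci(w - b)
        if np.any(b == 0):
            warnings.warn(
                f"{label}: zero base count in some run; percentage change undefined",
                stacklevel=2,
            )
            pm = plo = phi = float("nan")
        else:
            pm, plo, phi = mean_ci(100.0 * w / b)
        service_rows.append(
            {
                "service": label,
                "base_mean": bm, "base_ci_lower": blo, "base_ci_upper": bhi,
                "whatif_mean": wm, "whatif_ci_lower": wlo, "whatif_ci_upper": whi,
                "diff_mean": dm, "diff_ci_lower": dlo, "diff_ci_upper": dhi,
                "pct_change_mean": pm, "pct_change_ci_lower": plo,
                "pct_change_ci_upper": phi,
            }
        )
    avoidable_rows = []
    for repset in (base, whatif):
        cm, clo, chi = mean_ci(repset.avoidable_counts())
        pm, plo, phi = mean_ci(repset.avoidable_proportions_pct())
        avoidable_rows.append(
            {
                "scenario": repset.label,
                "count_mean": cm, "count_ci_lower": clo, "count_ci_upper": chi,
                "pct_mean": pm, "pct_ci_lower": plo, "pct_ci_upper": phi,
            }
        )
    dm, dlo, dhi = mean_ci(whatif.avoidable_counts() - base.avoidable_counts())
    avoidable_rows.append(
        {
            "scenario": "difference",
            "count_mean": dm, "count_ci_lower": dlo, "count_ci_upper": dhi,
            "pct_mean": float("nan"), "pct_ci_lower": float("nan"),
            "pct_ci_upper": float("nan"),
        }
    )
    fc_rows = []
    for service in [s for s in ServiceKind if s is not ServiceKind.INDEX_111]:
        for repset in (base, whatif):
            m, lo, hi = mean_ci(repset.first_contact_pct(service))
            fc_rows.append(
                {
                    "service": service.value, "scenario": repset.label,
                    "pct_mean": m, "pct_ci_lower": lo, "pct_ci_upper": hi,
                }
            )
    return ComparisonReport(
        services=pd.DataFrame(service_rows),
        avoidable=pd.DataFrame(avoidable_rows),
        first_contact=pd.DataFrame(fc_rows),
        metadata={
            "n_runs": base.n_runs,
            "base_master_seed": base.master_seed,
            "whatif_master_seed": whatif.master_seed,
            "ci_method": "normal approximation, mean +/- 1.96*sd/sqrt(n), paired by run index",
        },
    )


def trajectory_table(log: pd.DataFrame, depth: int = 5) -> pd.DataFrame:
    """Counts of ordered service chains (first ``depth`` interactions).

    Each patient contributes one chain: services in time order, truncated
    at ``depth``, with a terminal NO_FURTHER_CONTACT appended when the
    trajectory ended before the depth limit.  Suitable for Sankey
    rendering; chain counts sum to the number of patients.
    """
    ordered = log.sort_values(["patient_id", "timestamp"], kind="mergesort")
    chains: dict[tuple, int] = {}
    for _pid, grp in ordered.groupby("patient_id", sort=False):
        services = list(grp["service"])[:depth]
        if len(services) < depth:
            services.append(ServiceKind.NO_FURTHER_CONTACT.value)
        chain = tuple(services)
        chains[chain] = chains.get(chain, 0) + 1
    rows = [
        {"chain": " > ".join(chain), "count": count}
        for chain, count in sorted(chains.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["chain", "count"])


def hourly_profile(
    log: pd.DataFrame, start_weekday: int = clock.DEFAULT_START_WEEKDAY
) -> pd.DataFrame:
    """Index-call counts per (hour of day, weekday/weekend)."""
    index_rows = log[log["service"] == ServiceKind.INDEX_111.value]
    counts = {(h, w): 0 for h in range(24) for w in (False, True)}
    for t in index_rows["timestamp"].to_numpy(float):
        counts[(clock.hour_of(t), clock.is_weekend(t, start_weekday))] += 1
    rows = [
        {"hour": h, "is_weekend": w, "count": c}
        for (h, w), c in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["hour", "is_weekend", "count"])
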
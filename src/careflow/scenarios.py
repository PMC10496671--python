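"""Scenario (what-if) configuration.

The counterfactual of interest: every caller triaged to primary care
receives a guaranteed, timely primary-care contact, with no capacity
constraint.  It is realised as (a) every timely proportion set to 1 and
(b) the first transition out of the index call forced to PRIMARY_CARE —
the only reading under which 100% of callers access primary care.
Subsequent transitions are unchanged (they proceed from the
gp_first_contact = True stratum), so later ED/999/111 contacts — and
exit with no further contact — remain possible.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ScenarioFlags:
    """Engine switches distinguishing the base model from a counterfactual."""

    force_timely: bool = False
    force_primary_care_first: bool = False
    label: str = "base"


BASE_SCENARIO = ScenarioFlags(label="base")
WHAT_IF_LABEL = "what-if"


def apply_what_if(bundle):
    """Derive the guaranteed-timely-primary-care configuration.

    Returns ``(bundle_copy, flags)``: the copy has every p_timely set to 1;
    the flags make the engine route every caller's first hop to primary
    care.  All other tables are untouched.  Idempotent.
    """
    modified = bundle.copy()
    modified.timely = {code: 1.0 for code in modified.timely}
    modified.provenance = dict(modified.provenance, scenario=WHAT_IF_LABEL)
    flags = ScenarioFlags(
        force_timely=True, force_primary_care_first=True, label=WHAT_IF_LABEL
    )
    return modified, flags


def flags_for(name: str) -> ScenarioFlags:
    """Scenario flags by CLI name ('base' or 'what-if')."""
    if name == "base":
        return BASE_SCENARIO
    if name in (WHAT_IF_LABEL, "whatif", "what_if"):
        return ScenarioFlags(
            force_timely=True, force_primary_care_first=True, label=WHAT_IF_LABEL
        )
    raise ValueError(f"unknown scenario {name!r} (expected 'base' or 'what-if')")
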
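"""Intervention components: dose, reach, retention, enrollment.

Two multi-component obesity-prevention interventions are modeled:

* Three school physical-activity programs (a before-school program, a
  classroom-based program, and a walking/running program), each defined
  by an activity dose (minutes at a MET level), a reach (fraction of the
  student population receiving it), and a retention (fraction still
  participating at year end).
* Three out-of-school-time (OST) components delivered at the community
  after-school program: a beverage substitution (-60 kcal/day), an added
  activity bout (15 min at 4.5 METs), and a snack substitution
  (-68.25 kcal/day), each with reach 15% of attendees and retention 80%.

Reach is realized as Bernoulli enrollment over the eligible population;
retention as a Bernoulli dropout flag with a uniformly distributed
dropout day, so the expected fraction still active on the last day of a
365-day run equals the retention.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigurationError

COMPONENT_IDS = ("ASAP1", "ASAP2", "ASAP3", "DrinkRight", "MoveMore", "SnackSmart")
ACTIVITY_COMPONENTS = ("ASAP1", "ASAP2", "ASAP3", "MoveMore")
DIETARY_COMPONENTS = ("DrinkRight", "SnackSmart")
OST_COMPONENTS = ("DrinkRight", "MoveMore", "SnackSmart")

#: Retention presets.  The two sources for the school programs disagree on
#: programs 2 and 3; "text" is the default narrated parameterization,
#: "tabular" the tabulated one.  Both are preserved rather than silently
#: merged.
RETENTION_PRESETS = {
    "narrative": {"ASAP1": 0.80, "ASAP2": 0.80, "ASAP3": 0.90},
    "tabular": {"ASAP1": 0.80, "ASAP2": 0.90, "ASAP3": 0.80},
}


@dataclass(frozen=True)
class InterventionSpec:
    """One intervention component.

    Exactly one of (dose_minutes + dose_met) or dose_kcal is set:
    activity components insert minutes at a MET level, dietary components
    shift daily intake by a (negative) kcal amount.
    """

    component_id: str
    reach: float
    retention: float
    eligible_context: str            # "school" | "community"
    dose_minutes: int | None = None
    dose_met: float | None = None
    dose_kcal: float | None = None

    def __post_init__(self):
        if not (0.0 <= self.reach <= 1.0 and 0.0 <= self.retention <= 1.0):
            raise ConfigurationError("reach and retention must be in [0, 1]")
        activity = self.dose_minutes is not None or self.dose_met is not None
        dietary = self.dose_kcal is not None
        if activity == dietary:
            raise ConfigurationError(
                "exactly one of an activity dose (minutes+MET) or a dietary "
                "dose (kcal) must be set"
            )
        if activity and (self.dose_minutes is None or self.dose_met is None):
            raise ConfigurationError("activity dose needs both minutes and MET")
        if dietary and self.dose_kcal > 0:
            raise ConfigurationError("dietary dose must be a decrement (<= 0)")


@dataclass(frozen=True)
class Enrollment:
    """Enrollment state of one agent in one component.

    An agent is *active* on day d iff enrolled and (no dropout day or
    d < dropout_day).
    """

    agent_id: int
    component_id: str
    enrolled: bool
    dropout_day: int | None = None

    def active_on(self, day: int) -> bool:
        return self.enrolled and (self.dropout_day is None or day < self.dropout_day)


def default_specs(preset: str = "narrative") -> list[InterventionSpec]:
    """The default parameterization of all six components.

    School programs: program 1 (before school) 40 min @ 2.99 METs, reach
    10%; program 2 (classroom) 10 min @ 2.62 METs, reach 90%; program 3
    (walking/running) 30 min @ 4.96 METs, reach 75%.  Retention follows
    the chosen preset.  OST components: beverage substitution -60 kcal,
    added activity 15 min @ 4.5 METs, snack substitution -68.25 kcal; all
    with reach 15% and retention 80%.
    """
    if preset not in RETENTION_PRESETS:
        raise ConfigurationError(
            f"unknown retention preset {preset!r}; "
            f"choose from {sorted(RETENTION_PRESETS)}"
        )
    ret = RETENTION_PRESETS[preset]
    return [
        InterventionSpec("ASAP1", reach=0.10, retention=ret["ASAP1"],
                         eligible_context="school", dose_minutes=40, dose_met=2.99),
        InterventionSpec("ASAP2", reach=0.90, retention=ret["ASAP2"],
                         eligible_context="school", dose_minutes=10, dose_met=2.62),
        InterventionSpec("ASAP3", reach=0.75, retention=ret["ASAP3"],
                         eligible_context="school", dose_minutes=30, dose_met=4.96),
        InterventionSpec("DrinkRight", reach=0.15, retention=0.80,
                         eligible_context="community", dose_kcal=-60.0),
        InterventionSpec("MoveMore", reach=0.15, retention=0.80,
                         eligible_context="community", dose_minutes=15,
                         dose_met=4.5),
        InterventionSpec("SnackSmart", reach=0.15, retention=0.80,
                         eligible_context="community", dose_kcal=-68.25),
    ]


def spec_by_id(specs: list[InterventionSpec], component_id: str) -> InterventionSpec:
    for s in specs:
        if s.component_id == component_id:
            return s
    raise ConfigurationError(f"unknown component {component_id!r}")


def with_overrides(spec: InterventionSpec, **kwargs) -> InterventionSpec:
    """Copy a spec with selected fields overridden (reach, retention, dose)."""
    return replace(spec, **kwargs)


def assign_enrollment(agents, spec: InterventionSpec, seed: int,
                      n_days: int = 365) -> list[Enrollment]:
    """Stochastic enrollment and dropout for one component.

    Eligibility: community components only reach after-school attendees;
    school components reach everyone.  Each eligible agent enrolls with
    probability ``reach``; each enrollee independently drops out with
    probability ``1 - retention``, at a day uniform over [1, n_days].
    Deterministic for a fixed seed (draw order: enrollment flags, dropout
    flags, dropout days).
    """
    rng = np.random.default_rng(seed)
    eligible = [
        a for a in agents
        if spec.eligible_context == "school" or a.attends_afterschool
    ]
    n = len(eligible)
    enrolled = rng.random(n) < spec.reach
    drops = rng.random(n) < (1.0 - spec.retention)
    drop_days = rng.integers(1, n_days + 1, size=n)
    out = []
    for i, a in enumerate(eligible):
        if enrolled[i]:
            day = int(drop_days[i]) if drops[i] else None
            out.append(Enrollment(a.id, spec.component_id, True, day))
        else:
            out.append(Enrollment(a.id, spec.component_id, False, None))
    return out


def apply_dietary_dose(active_specs, attends_community_today: bool) -> float:
    """Total kcal adjustment from active dietary components for one agent-day.

    Dietary doses apply only on days the agent actually attends the
    community program; components stack additively.
    """
    if not attends_community_today:
        return 0.0
    return sum(
        s.dose_kcal for s in active_specs
        if s.dose_kcal is not None
    )
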
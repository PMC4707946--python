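"""Daily movement and minute-resolution activity timelines.

Every simulated day has the same clock: agents are at home overnight, move
to school at 08:00, leave school at 15:00 for either the community
after-school program (attendees) or home, and everyone is home from 19:00.
Sleep occupies 600 minutes at MET 1.0 (21:00-07:00); all remaining time is
sedentary filler at MET 1.5 unless the town's activity pattern or an
active intervention bout assigns an elevated MET.

Intervention bouts *replace* sedentary minutes inside their program
window, so the day always sums to 1440 minutes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, ConsistencyError
from .reference import (
    MET_SEDENTARY,
    MET_SLEEP,
    ReferenceBundle,
    SEGMENT_MINUTES,
)

logger = logging.getLogger(__name__)

MINUTES_PER_DAY = 1440

#: Minute-of-day bounds [start, end) for the awake segments.
SEGMENT_BOUNDS = {
    "home_morning": (420, 480),
    "school": (480, 900),
    "community": (900, 1140),
    "home_evening": (1140, 1260),
}
#: Sleep blocks (21:00-24:00 and 00:00-07:00), 600 minutes total.
SLEEP_BLOCKS = ((0, 420), (1260, 1440))

#: Program window for each activity intervention component: the before-
#: school program runs in the morning home hour, classroom and walking
#: programs during school, and the out-of-school-time activity component
#: within community hours.
COMPONENT_WINDOW = {
    "ASAP1": "home_morning",
    "ASAP2": "school",
    "ASAP3": "school",
    "MoveMore": "community",
}

#: MVPA reporting cut points (METs).  These are definitional constants for
#: reporting moderate-to-vigorous activity under the two program
#: conventions; they do not enter the dynamics.
MVPA_MET_CUTOFF_SCHOOL_PROGRAMS = 6.0
MVPA_MET_CUTOFF_OST_PROGRAMS = 4.5

_CONTEXTS = ("home", "school", "community")


@dataclass
class DayTimeline:
    """Minute-resolution (context, MET) assignment for one agent-day."""

    mets: np.ndarray                 # shape (1440,), MET per minute
    contexts: np.ndarray             # shape (1440,), int8 index into _CONTEXTS
    truncated_bouts: list[str] = field(default_factory=list)

    def pal(self) -> float:
        return float(self.mets.sum() / MINUTES_PER_DAY)

    def context_at_minute(self, minute: int) -> str:
        return _CONTEXTS[int(self.contexts[minute])]

    def blocks(self) -> list[tuple[str, int, float]]:
        """Run-length encode the day as ordered (context, minutes, MET)."""
        out = []
        start = 0
        for i in range(1, MINUTES_PER_DAY + 1):
            if (
                i == MINUTES_PER_DAY
                or self.mets[i] != self.mets[start]
                or self.contexts[i] != self.contexts[start]
            ):
                out.append(
                    (_CONTEXTS[int(self.contexts[start])], i - start,
                     float(self.mets[start]))
                )
                start = i
        return out

    def validate(self) -> None:
        if self.mets.shape != (MINUTES_PER_DAY,):
            raise ConsistencyError("timeline must cover exactly 1440 minutes")
        if np.any(self.mets < 1.0):
            raise ConsistencyError("MET below 1.0 in timeline")


@dataclass
class Environment:
    """Static town layout: homes, schools, communities, and assignments.

    The layout is stylized and drives no dynamics; it exists so runs can
    report which home/school each agent belongs to.
    """

    n_homes: int = 56
    n_schools: int = 12
    n_communities: int = 1
    home_assignment: dict[int, int] = field(default_factory=dict)
    school_assignment: dict[int, int] = field(default_factory=dict)

    def __post_init__(self):
        if min(self.n_homes, self.n_schools, self.n_communities) < 1:
            raise ConfigurationError("environment counts must be >= 1")

    def assign(self, agent_ids, seed: int) -> None:
        rng = np.random.default_rng(seed)
        for aid in agent_ids:
            self.home_assignment[aid] = int(rng.integers(self.n_homes))
            self.school_assignment[aid] = int(rng.integers(self.n_schools))


def context_at(agent, hour: int) -> str:
    """Context of an agent at a clock hour.

    [0, 8) home; [8, 15) school; [15, 19) community for after-school
    attendees, home otherwise; [19, 24) home.
    """
    if not (0 <= hour < 24):
        raise ConfigurationError(f"hour must be in [0, 24), got {hour}")
    if 8 <= hour < 15:
        return "school"
    if 15 <= hour < 19 and agent.attends_afterschool:
        return "community"
    return "home"


def _base_timeline(attends: bool) -> DayTimeline:
    mets = np.full(MINUTES_PER_DAY, MET_SEDENTARY)
    contexts = np.zeros(MINUTES_PER_DAY, dtype=np.int8)  # home
    for lo, hi in SLEEP_BLOCKS:
        mets[lo:hi] = MET_SLEEP
    lo, hi = SEGMENT_BOUNDS["school"]
    contexts[lo:hi] = _CONTEXTS.index("school")
    if attends:
        lo, hi = SEGMENT_BOUNDS["community"]
        contexts[lo:hi] = _CONTEXTS.index("community")
    return DayTimeline(mets=mets, contexts=contexts)


def _place_block(tl: DayTimeline, window: tuple[int, int], minutes: int,
                 met: float, label: str) -> None:
    """Replace up to ``minutes`` sedentary minutes in a window with ``met``."""
    lo, hi = window
    free = np.flatnonzero(tl.mets[lo:hi] == MET_SEDENTARY) + lo
    if len(free) < minutes:
        logger.warning(
            "bout %r truncated: requested %d min, only %d sedentary min in window",
            label, minutes, len(free),
        )
        tl.truncated_bouts.append(label)
        minutes = len(free)
    tl.mets[free[:minutes]] = met


def build_day_timeline(agent, profile, bundle: ReferenceBundle,
                       interventions=()) -> DayTimeline:
    """Build one agent-day timeline for the agent's town.

    ``interventions`` is the set of activity-component specs active for
    this agent today (dietary components do not alter the timeline).
    Baseline town activity blocks are laid down first, then intervention
    bouts replace remaining sedentary minutes inside their program window.
    Non-attendees spend community hours at home (sedentary baseline) and
    never receive out-of-school-time bouts.
    """
    tl = _base_timeline(agent.attends_afterschool)
    patterns = bundle.activity_for(profile.town_type)
    for segment, (lo, hi) in SEGMENT_BOUNDS.items():
        if segment == "community" and not agent.attends_afterschool:
            continue
        pat = patterns.get(segment)
        if pat is None or pat.minutes == 0:
            continue
        if pat.minutes > SEGMENT_MINUTES[segment]:
            raise ConsistencyError(
                f"pattern for {segment} exceeds segment length"
            )
        _place_block(tl, (lo, hi), pat.minutes, pat.met_level,
                     f"baseline:{segment}")

    for spec in interventions:
        if spec.dose_minutes is None:
            continue  # dietary component
        window_name = COMPONENT_WINDOW.get(spec.component_id)
        if window_name is None:
            raise ConfigurationError(
                f"no program window for component {spec.component_id!r}"
            )
        if window_name == "community" and not agent.attends_afterschool:
            continue
        _place_block(tl, SEGMENT_BOUNDS[window_name], spec.dose_minutes,
                     spec.dose_met, spec.component_id)

    tl.validate()
    return tl


def mvpa_minutes(tl: DayTimeline, met_cutoff: float) -> int:
    """Reporting helper: minutes at or above an MVPA MET cut point."""
    return int(np.count_nonzero(tl.mets >= met_cutoff))
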
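"""Energy-balance physiology of a simulated child.

The model is a hybrid of standard pediatric energy equations:

* Resting metabolic rate (RMR) from the age/sex-banded Schofield linear
  equations in weight W (kg) and height H (cm), in kcal/day.
* Daily expenditure TEE = RMR x PAL, where PAL is the time-weighted mean
  MET over the 1440 minutes of the day.
* Daily intake = RMR x intake multiplier (+ any intervention kcal
  adjustment, floored at zero).
* The daily calorie gap (intake - expenditure) converts to weight change
  at 7,700 kcal per kilogram.
* Height grows at an age/sex-conditional reference velocity, uncoupled
  from energy balance; BMI follows from the identity W / (H/100)^2.

All functions here are pure: the engine owns state and randomness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import reference
from .errors import ConsistencyError, GridRangeError
from .reference import ReferenceBundle

logger = logging.getLogger(__name__)

#: Calorie surplus required to gain one kilogram of body mass.
KCAL_PER_KG = 7700.0

#: Weight floor (kg): pathological configurations cannot drive an agent
#: below this mass; hitting it is logged, never silent.
MIN_WEIGHT_KG = 10.0

MINUTES_PER_DAY = 1440

# Schofield coefficients (weight, height, intercept) by sex and age band.
# The two printed bands meet at exactly age 10; by convention here an agent
# of exactly 10.0 years falls in the older band.  The bands are linear and
# deliberately NOT continuous at the boundary.
SCHOFIELD = {
    ("male", "3-10"): (19.59, 1.303, 414.9),
    ("male", "10-18"): (16.25, 1.372, 515.5),
    ("female", "3-10"): (16.969, 1.618, 371.2),
    ("female", "10-18"): (8.365, 4.65, 200.0),
}


@dataclass
class DailyLedger:
    """Per-agent per-day energy accounting record."""

    agent_id: int
    day: int
    intake_kcal: float
    expenditure_kcal: float
    calorie_gap_kcal: float
    pal: float
    contexts: list[tuple[str, int, float]]  # (segment, minutes, MET)


def schofield_rmr(sex: str, age_years: float, weight_kg: float,
                  height_cm: float) -> float:
    """Resting metabolic rate (kcal/day) from the Schofield equations.

    Parameters
    ----------
    sex : {"male", "female"}
    age_years : age in years; must lie in [3, 18)
    weight_kg, height_cm : body size; must be non-negative

    Notes
    -----
    Boys 3-10:  19.59 W + 1.303 H + 414.9
    Boys 10-18: 16.25 W + 1.372 H + 515.5
    Girls 3-10: 16.969 W + 1.618 H + 371.2
    Girls 10-18: 8.365 W + 4.65 H + 200.0
    """
    if not (3.0 <= age_years < 18.0):
        raise GridRangeError(f"age {age_years} outside Schofield range [3, 18)")
    if weight_kg < 0 or height_cm < 0:
        raise ValueError("weight and height must be non-negative")
    band = "3-10" if age_years < 10.0 else "10-18"
    cw, ch, c0 = SCHOFIELD[(sex, band)]
    return cw * weight_kg + ch * height_cm + c0


def schofield_rmr_vec(male: np.ndarray, age_years: np.ndarray,
                      weight_kg: np.ndarray, height_cm: np.ndarray) -> np.ndarray:
    """Vectorized Schofield RMR over agent arrays (``male`` is boolean)."""
    if np.any(age_years < 3.0) or np.any(age_years >= 18.0):
        bad = int(np.argmax((age_years < 3.0) | (age_years >= 18.0)))
        raise GridRangeError(
            f"agent index {bad}: age {age_years[bad]:.2f} outside [3, 18)"
        )
    young = age_years < 10.0
    cw = np.where(male, np.where(young, 19.59, 16.25),
                  np.where(young, 16.969, 8.365))
    ch = np.where(male, np.where(young, 1.303, 1.372),
                  np.where(young, 1.618, 4.65))
    c0 = np.where(male, np.where(young, 414.9, 515.5),
                  np.where(young, 371.2, 200.0))
    return cw * weight_kg + ch * height_cm + c0


def compute_pal(mets: np.ndarray) -> float:
    """Time-weighted physical activity level over one day.

    ``mets`` is the minute-resolution MET assignment (length 1440, all
    values >= 1.0); the PAL is its arithmetic mean.
    """
    mets = np.asarray(mets, dtype=float)
    if mets.shape != (MINUTES_PER_DAY,):
        raise ConsistencyError(
            f"MET assignment must cover exactly {MINUTES_PER_DAY} minutes, "
            f"got shape {mets.shape}"
        )
    if np.any(mets < 1.0):
        raise ConsistencyError("MET values below 1.0 are not physical")
    return float(mets.sum() / MINUTES_PER_DAY)


def total_energy_expenditure(rmr: float, pal: float) -> float:
    """TEE (kcal/day) = RMR x PAL."""
    if rmr <= 0:
        raise ValueError("rmr must be positive")
    if pal < 1.0:
        raise ValueError("pal must be >= 1")
    return rmr * pal


def daily_intake(rmr: float, multiplier: float, kcal_adjustment: float = 0.0) -> float:
    """Daily caloric intake: RMR x multiplier plus adjustment, floored at 0.

    The multiplier is an agent property (intake expressed as a multiple of
    resting metabolic rate); intervention decrements enter additively via
    ``kcal_adjustment`` (negative for dietary components).
    """
    if rmr <= 0:
        raise ValueError("rmr must be positive")
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    return max(rmr * multiplier + kcal_adjustment, 0.0)


def apply_energy_balance(weight_kg: float, calorie_gap_kcal: float,
                         min_weight_kg: float = MIN_WEIGHT_KG) -> float:
    """New weight after one day's calorie gap at 7,700 kcal/kg.

    The result is floored at ``min_weight_kg`` (with a logged warning) to
    keep pathological configurations physical.
    """
    if weight_kg <= 0:
        raise ValueError("weight must be positive")
    new_weight = weight_kg + calorie_gap_kcal / KCAL_PER_KG
    if new_weight < min_weight_kg:
        logger.warning(
            "weight floor triggered: %.2f kg -> floored at %.2f kg",
            new_weight, min_weight_kg,
        )
        return min_weight_kg
    return new_weight


def grow_height(agent, bundle: ReferenceBundle):
    """Advance an agent one day: height growth, aging, BMI recompute.

    Height increases by the reference velocity for the agent's (age, sex);
    growth is uncoupled from energy balance.  Weight is untouched.
    Returns the same agent object, mutated.
    """
    month = reference.nearest_month(agent.age_days)
    vel = reference.lookup_velocity(bundle, month, agent.sex)
    agent.height_cm += vel
    agent.age_days += 1
    agent.bmi = bmi_from(agent.weight_kg, agent.height_cm)
    return agent


def bmi_from(weight_kg: float, height_cm: float) -> float:
    """BMI identity, kg/m^2."""
    return weight_kg / (height_cm / 100.0) ** 2


def hourly_expenditure(mets: np.ndarray, rmr: float) -> np.ndarray:
    """Expenditure per clock hour (24 values, kcal).

    Hour h spends rmr x sum(met[60h:60h+60]) / 1440 kcal, so the 24 hourly
    records sum exactly to the daily TEE = rmr x PAL.
    """
    mets = np.asarray(mets, dtype=float)
    if mets.shape != (MINUTES_PER_DAY,):
        raise ConsistencyError("MET assignment must cover exactly 1440 minutes")
    return rmr * mets.reshape(24, 60).sum(axis=1) / MINUTES_PER_DAY


#: Clock hours at which daily intake is booked (breakfast at home, lunch
#: at school, dinner at home), one third each.
MEAL_HOURS = (7, 12, 19)


def hourly_intake(intake_kcal: float) -> np.ndarray:
    """Intake per clock hour (24 values summing to the daily intake)."""
    out = np.zeros(24)
    for h in MEAL_HOURS:
        out[h] = intake_kcal / len(MEAL_HOURS)
    return out
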
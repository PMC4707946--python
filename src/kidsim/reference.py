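"""Synthetic reference bundles: growth references and behaviour patterns.

Real simulations of childhood growth are parameterized from national
growth charts (LMS tables for BMI-for-age), survey-derived activity
patterns, and intake distributions.  Those inputs are not shipped with
this package; instead this module generates *synthetic* reference bundles
with the same structure — smooth, monotone LMS and height-for-age curves
over a monthly (age, sex) grid, plus stylized activity patterns for the
three town types — so that every other module is fully testable without
any download.  A user may substitute a real bundle in the same file
format.

The bundle file is a single JSON (or YAML) document with a ``version``
field and arrays ``lms``, ``heights``, ``growth``, ``activity`` plus the
scalar intake-multiplier parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError, GridRangeError

SEXES = ("male", "female")
TOWN_TYPES = ("A", "B", "C")

#: Awake day segments and their lengths in minutes.  Sleep (600 min at
#: MET 1.0) is carried separately; it occupies 21:00-07:00 inside home hours.
SEGMENT_MINUTES = {
    "home_morning": 60,   # 07:00-08:00
    "school": 420,        # 08:00-15:00
    "community": 240,     # 15:00-19:00 (after-school attendees only)
    "home_evening": 120,  # 19:00-21:00
}
SLEEP_MINUTES = 600
MET_SLEEP = 1.0
MET_SEDENTARY = 1.5

#: Default monthly age grid (6 y through 18 y).  The simulator only
#: initializes agents at ages 6-12, but the grid extends well past 13 y so
#: agents can age through multi-year runs without leaving the reference.
AGE_MIN_MONTHS = 72
AGE_MAX_MONTHS = 216

DAYS_PER_MONTH = 365.25 / 12.0

BUNDLE_VERSION = "1"


@dataclass(frozen=True)
class LMSRecord:
    """One (age, sex) cell of a BMI-for-age LMS reference.

    L is the Box-Cox power, M the median BMI (kg/m^2) and S the
    coefficient of variation of the age/sex-conditional BMI distribution.
    """

    age_months: int
    sex: str
    L: float
    M: float
    S: float


@dataclass(frozen=True)
class HeightRecord:
    """Median height (cm) and coefficient of variation at one (age, sex)."""

    age_months: int
    sex: str
    median_cm: float
    cv: float


@dataclass(frozen=True)
class GrowthVelocityRecord:
    """Height growth velocity in cm per day at one (age, sex)."""

    age_months: int
    sex: str
    height_velocity: float


@dataclass(frozen=True)
class ActivityPattern:
    """Elevated-activity block for one town type and day segment.

    ``minutes`` of the segment are spent at ``met_level``; the remainder
    of the segment is sedentary filler at MET 1.5.  The sleep segment is
    always 600 minutes at MET 1.0.
    """

    town_type: str
    segment: str
    met_level: float
    minutes: int


@dataclass
class ReferenceBundle:
    """Complete reference-data bundle for a simulation run."""

    version: str
    profile: str
    lms: list[LMSRecord]
    heights: list[HeightRecord]
    growth: list[GrowthVelocityRecord]
    activity: list[ActivityPattern]
    intake_multiplier_mean: dict[str, float]
    intake_multiplier_sd: float
    _cache: dict = field(default_factory=dict, compare=False, repr=False)

    # -- grid access -----------------------------------------------------

    @property
    def age_min_months(self) -> int:
        return min(r.age_months for r in self.lms)

    @property
    def age_max_months(self) -> int:
        return max(r.age_months for r in self.lms)

    def lms_arrays(self) -> tuple[np.ndarray, dict[str, dict[str, np.ndarray]]]:
        """Return (sorted month grid, per-sex {L, M, S} arrays) for fast lookup."""
        if "lms" not in self._cache:
            ages = np.array(sorted({r.age_months for r in self.lms}))
            per_sex = {}
            for sex in SEXES:
                recs = sorted(
                    (r for r in self.lms if r.sex == sex), key=lambda r: r.age_months
                )
                per_sex[sex] = {
                    "L": np.array([r.L for r in recs]),
                    "M": np.array([r.M for r in recs]),
                    "S": np.array([r.S for r in recs]),
                }
            self._cache["lms"] = (ages, per_sex)
        return self._cache["lms"]

    def height_arrays(self) -> tuple[np.ndarray, dict[str, dict[str, np.ndarray]]]:
        if "heights" not in self._cache:
            ages = np.array(sorted({r.age_months for r in self.heights}))
            per_sex = {}
            for sex in SEXES:
                recs = sorted(
                    (r for r in self.heights if r.sex == sex),
                    key=lambda r: r.age_months,
                )
                per_sex[sex] = {
                    "median_cm": np.array([r.median_cm for r in recs]),
                    "cv": np.array([r.cv for r in recs]),
                }
            self._cache["heights"] = (ages, per_sex)
        return self._cache["heights"]

    def velocity_arrays(self) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        if "growth" not in self._cache:
            ages = np.array(sorted({r.age_months for r in self.growth}))
            per_sex = {}
            for sex in SEXES:
                recs = sorted(
                    (r for r in self.growth if r.sex == sex),
                    key=lambda r: r.age_months,
                )
                per_sex[sex] = np.array([r.height_velocity for r in recs])
            self._cache["growth"] = (ages, per_sex)
        return self._cache["growth"]

    def activity_for(self, town_type: str) -> dict[str, ActivityPattern]:
        """Activity patterns for one town, keyed by segment name."""
        return {p.segment: p for p in self.activity if p.town_type == town_type}

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "version": self.version,
            "profile": self.profile,
            "lms": [asdict(r) for r in self.lms],
            "heights": [asdict(r) for r in self.heights],
            "growth": [asdict(r) for r in self.growth],
            "activity": [asdict(r) for r in self.activity],
            "intake_multiplier_mean": dict(self.intake_multiplier_mean),
            "intake_multiplier_sd": self.intake_multiplier_sd,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ReferenceBundle":
        if "version" not in d:
            raise ConfigurationError("bundle document lacks required 'version' field")
        return cls(
            version=str(d["version"]),
            profile=d.get("profile", "unknown"),
            lms=[LMSRecord(**r) for r in d["lms"]],
            heights=[HeightRecord(**r) for r in d["heights"]],
            growth=[GrowthVelocityRecord(**r) for r in d["growth"]],
            activity=[ActivityPattern(**r) for r in d["activity"]],
            intake_multiplier_mean={
                k: float(v) for k, v in d["intake_multiplier_mean"].items()
            },
            intake_multiplier_sd=float(d["intake_multiplier_sd"]),
        )

    def __eq__(self, other) -> bool:  # cache excluded from equality
        if not isinstance(other, ReferenceBundle):
            return NotImplemented
        return self.to_dict() == other.to_dict()


def save_bundle(bundle: ReferenceBundle, path: str | Path) -> None:
    """Write a bundle to JSON (default) or YAML (by .yaml/.yml suffix)."""
    path = Path(path)
    doc = bundle.to_dict()
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
    else:
        path.write_text(json.dumps(doc, indent=1))


def load_bundle(path: str | Path) -> ReferenceBundle:
    path = Path(path)
    text = path.read_text()
    doc = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return ReferenceBundle.from_dict(doc)


# ---------------------------------------------------------------------------
# Synthetic generation
# ---------------------------------------------------------------------------

# Smooth quadratic curves in a = age_months - 72 emulating the *shape* of
# growth-chart references.  Coefficients receive a small seeded jitter so
# distinct seeds yield distinct (but always valid) bundles.
_MEDIAN_BMI = {  # (intercept, linear, quadratic) in kg/m^2
    "male": (15.3, 0.018, 8.0e-5),
    "female": (15.1, 0.016, 7.0e-5),
}
_BOXCOX_L = {"male": (-1.9, 0.002), "female": (-1.8, 0.0018)}
_BMI_S = {"male": (0.105, 1.5e-4), "female": (0.110, 1.4e-4)}
_MEDIAN_HEIGHT = {  # cm
    "male": (115.5, 0.42, 2.0e-4),
    "female": (114.8, 0.43, -3.0e-4),
}
_HEIGHT_CV = 0.04

#: Stylized elevated-activity defaults (MET level, minutes) per town and
#: awake segment.  Town A is the "average" town; town B has no in-school
#: physical education but some after-school activity; town C matches A in
#: school and exceeds it after school.  The magnitudes are assumptions —
#: the town contrasts are qualitative in origin.
_ACTIVITY_DEFAULTS: dict[str, dict[str, tuple[float, int]]] = {
    "A": {
        "home_morning": (3.0, 15),
        "school": (5.0, 90),
        "community": (4.0, 45),
        "home_evening": (3.0, 30),
    },
    "B": {
        "home_morning": (3.0, 15),
        "school": (5.0, 0),
        "community": (4.0, 45),
        "home_evening": (3.0, 30),
    },
    "C": {
        "home_morning": (3.0, 15),
        "school": (5.0, 90),
        "community": (4.0, 75),
        "home_evening": (3.0, 30),
    },
}

#: Default intake multiplier (daily intake as a multiple of RMR) for towns
#: A and B, and the fixed A-to-C offset.  Town C's multiplier is exactly
#: 0.01 below town A's, reflecting slightly healthier eating habits.
DEFAULT_INTAKE_MULTIPLIER = 1.6
TOWN_C_MULTIPLIER_OFFSET = 0.01
DEFAULT_INTAKE_MULTIPLIER_SD = 0.1


def _jitter(rng: np.random.Generator, base: float, scale: float) -> float:
    return float(base + rng.normal(0.0, scale))


def generate_reference_bundle(seed: int, profile: str = "default") -> ReferenceBundle:
    """Generate a complete synthetic reference bundle.

    Deterministic for a fixed ``seed``.  The only built-in profile is
    ``"default"``: a monthly grid over ages 72-216 months for both sexes,
    strictly increasing median BMI and height curves, non-negative growth
    velocities, and the three stylized town activity patterns.

    Raises
    ------
    ConfigurationError
        If ``profile`` is not a known profile name.
    """
    if profile != "default":
        raise ConfigurationError(f"unknown reference profile: {profile!r}")
    rng = np.random.default_rng(seed)

    months = np.arange(AGE_MIN_MONTHS, AGE_MAX_MONTHS + 1)
    lms: list[LMSRecord] = []
    heights: list[HeightRecord] = []
    growth: list[GrowthVelocityRecord] = []
    for sex in SEXES:
        m0, m1, m2 = _MEDIAN_BMI[sex]
        m0 = _jitter(rng, m0, 0.05)
        m1 = max(1e-4, _jitter(rng, m1, 0.0005))
        l0, l1 = _BOXCOX_L[sex]
        l0 = _jitter(rng, l0, 0.02)
        s0, s1 = _BMI_S[sex]
        s0 = max(0.05, _jitter(rng, s0, 0.002))
        h0, h1, h2 = _MEDIAN_HEIGHT[sex]
        h0 = _jitter(rng, h0, 0.3)
        h1 = max(0.05, _jitter(rng, h1, 0.005))
        a = months - AGE_MIN_MONTHS
        for age, ai in zip(months.tolist(), a.tolist()):
            lms.append(
                LMSRecord(
                    age_months=int(age),
                    sex=sex,
                    L=round(l0 + l1 * ai, 6),
                    M=round(m0 + m1 * ai + m2 * ai * ai, 6),
                    S=round(s0 + s1 * ai, 6),
                )
            )
            heights.append(
                HeightRecord(
                    age_months=int(age),
                    sex=sex,
                    median_cm=round(h0 + h1 * ai + h2 * ai * ai, 6),
                    cv=_HEIGHT_CV,
                )
            )
            # velocity = d(height)/d(age in days); derivative of the same
            # median curve, so integrated growth tracks the reference
            vel = (h1 + 2.0 * h2 * ai) / DAYS_PER_MONTH
            growth.append(
                GrowthVelocityRecord(
                    age_months=int(age), sex=sex, height_velocity=round(max(vel, 0.0), 9)
                )
            )

    activity: list[ActivityPattern] = []
    for town in TOWN_TYPES:
        for segment, (met, minutes) in _ACTIVITY_DEFAULTS[town].items():
            activity.append(
                ActivityPattern(
                    town_type=town, segment=segment, met_level=met, minutes=minutes
                )
            )
        activity.append(
            ActivityPattern(
                town_type=town, segment="sleep", met_level=MET_SLEEP,
                minutes=SLEEP_MINUTES,
            )
        )

    mean_a = DEFAULT_INTAKE_MULTIPLIER
    multipliers = {
        "A": mean_a,
        "B": mean_a,
        "C": mean_a - TOWN_C_MULTIPLIER_OFFSET,
    }
    return ReferenceBundle(
        version=BUNDLE_VERSION,
        profile=profile,
        lms=lms,
        heights=heights,
        growth=growth,
        activity=activity,
        intake_multiplier_mean=multipliers,
        intake_multiplier_sd=DEFAULT_INTAKE_MULTIPLIER_SD,
    )


# ---------------------------------------------------------------------------
# Lookup
# ---------------------------------------------------------------------------


def nearest_month(age_days: float | np.ndarray) -> np.ndarray | int:
    """Nearest grid month for an age in days, ties going to the younger month."""
    m = np.asarray(age_days, dtype=float) / DAYS_PER_MONTH
    out = np.ceil(m - 0.5).astype(int)
    return out if out.ndim else int(out)

def _check_range(bundle: ReferenceBundle, age_months: int) -> None:
    if age_months < bundle.age_min_months or age_months > bundle.age_max_months:
        raise GridRangeError(
            f"age {age_months} months outside bundle grid "
            f"[{bundle.age_min_months}, {bundle.age_max_months}]"
        )


def lookup_lms(bundle: ReferenceBundle, age_months: int, sex: str) -> LMSRecord:
    """LMS record for (age, sex); nearest-age on the grid, ties to younger."""
    if sex not in SEXES:
        raise ConfigurationError(f"unknown sex: {sex!r}")
    _check_range(bundle, age_months)
    ages, per_sex = bundle.lms_arrays()
    idx = int(np.argmin(np.abs(ages - age_months)))
    # argmin ties already resolve to the younger (first) age
    p = per_sex[sex]
    return LMSRecord(
        age_months=int(ages[idx]), sex=sex,
        L=float(p["L"][idx]), M=float(p["M"][idx]), S=float(p["S"][idx]),
    )


def lookup_height(bundle: ReferenceBundle, age_months: int, sex: str) -> HeightRecord:
    if sex not in SEXES:
        raise ConfigurationError(f"unknown sex: {sex!r}")
    _check_range(bundle, age_months)
    ages, per_sex = bundle.height_arrays()
    idx = int(np.argmin(np.abs(ages - age_months)))
    p = per_sex[sex]
    return HeightRecord(
        age_months=int(ages[idx]), sex=sex,
        median_cm=float(p["median_cm"][idx]), cv=float(p["cv"][idx]),
    )


def lookup_velocity(bundle: ReferenceBundle, age_months: int, sex: str) -> float:
    """Height growth velocity (cm/day) for (age, sex)."""
    if sex not in SEXES:
        raise ConfigurationError(f"unknown sex: {sex!r}")
    _check_range(bundle, age_months)
    ages, per_sex = bundle.velocity_arrays()
    idx = int(np.argmin(np.abs(ages - age_months)))
    return float(per_sex[sex][idx])
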
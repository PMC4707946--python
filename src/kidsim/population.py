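"""Agent population generation and anthropometry.

Initial BMI is drawn through the LMS (Box-Cox) growth-reference
transform: a standard normal deviate z maps to

    BMI = M (1 + L S z)^(1/L)        (L != 0)
    BMI = M exp(S z)                 (L == 0)

where L, M, S come from the reference bundle, conditional on age and sex.
Town types shift the median M: town C uses the reference ("pre-epidemic")
median directly, town A adds a current-population offset, and town B sits
exactly 0.5 kg/m^2 above town A.  Weight follows from BMI and height;
height is drawn independently around the reference median height-for-age.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import physiology, reference
from .errors import ConfigurationError, DomainError, GridRangeError
from .reference import ReferenceBundle

#: Fraction of boys in a generated population (census-style default).
MALE_FRACTION = 0.511

#: Default fraction of agents attending a community after-school program.
DEFAULT_AFTERSCHOOL_FRACTION = 0.15

#: Default current-population offset (kg/m^2) added to the reference BMI
#: median for town A; town B adds a further 0.5.  Town C uses the
#: reference median unshifted.
DEFAULT_CURRENT_POPULATION_OFFSET = 1.0

#: Town B's BMI median exceeds town A's by exactly this much (kg/m^2).
TOWN_B_SHIFT = 0.5

#: Weight-status cut points on the reference BMI-for-age distribution
#: (CDC convention for children): overweight at the 85th percentile,
#: obese at the 95th.
OVERWEIGHT_PERCENTILE = 85.0
OBESE_PERCENTILE = 95.0

DAYS_PER_YEAR = 365.25


@dataclass
class Agent:
    """One simulated child."""

    id: int
    sex: str                      # "male" | "female"
    age_days: int
    height_cm: float
    weight_kg: float
    bmi: float
    rmr_kcal: float
    intake_multiplier: float
    attends_afterschool: bool
    #: component_id -> dropout day (None if retained all year)
    enrollments: dict[str, int | None] = field(default_factory=dict)

    @property
    def age_years(self) -> float:
        return self.age_days / DAYS_PER_YEAR


@dataclass(frozen=True)
class TownProfile:
    """Per-town-type parameterization.

    ``bmi_median_shift`` is relative to town A (A: 0, B: +0.5);
    ``current_population_offset`` lifts the reference median to the
    current-population level (0 for town C, which represents a
    pre-epidemic distribution).
    """

    town_type: str
    bmi_median_shift: float
    current_population_offset: float
    intake_multiplier_mean: float
    intake_multiplier_sd: float

    @classmethod
    def from_bundle(
        cls,
        town_type: str,
        bundle: ReferenceBundle,
        current_population_offset: float = DEFAULT_CURRENT_POPULATION_OFFSET,
    ) -> "TownProfile":
        if town_type not in reference.TOWN_TYPES:
            raise ConfigurationError(f"unknown town type: {town_type!r}")
        shift = {"A": 0.0, "B": TOWN_B_SHIFT, "C": 0.0}[town_type]
        offset = 0.0 if town_type == "C" else current_population_offset
        return cls(
            town_type=town_type,
            bmi_median_shift=shift,
            current_population_offset=offset,
            intake_multiplier_mean=bundle.intake_multiplier_mean[town_type],
            intake_multiplier_sd=bundle.intake_multiplier_sd,
        )

    def median_bmi(self, bundle: ReferenceBundle, age_months: int, sex: str) -> float:
        """Town-adjusted initialization median BMI at one (age, sex)."""
        rec = reference.lookup_lms(bundle, age_months, sex)
        return rec.M + self.current_population_offset + self.bmi_median_shift


# ---------------------------------------------------------------------------
# LMS transform
# ---------------------------------------------------------------------------


def lms_quantile(L: float, M: float, S: float, z):
    """Map standard-normal deviate(s) z to BMI through the LMS transform.

    Accepts scalars or arrays for ``z``.  Raises :class:`DomainError` when
    1 + L S z <= 0 (outside the Box-Cox domain for L != 0).
    """
    if M <= 0 or S <= 0:
        raise DomainError("M and S must be positive")
    z = np.asarray(z, dtype=float)
    if L == 0.0:
        out = M * np.exp(S * z)
    else:
        base = 1.0 + L * S * z
        if np.any(base <= 0.0):
            raise DomainError(
                f"z outside valid range for L={L}, S={S}: 1 + L*S*z must be > 0"
            )
        out = M * base ** (1.0 / L)
    return float(out) if out.ndim == 0 else out


def lms_zscore(L: float, M: float, S: float, bmi):
    """Invert the LMS transform: BMI -> standard-normal z-score."""
    if M <= 0 or S <= 0:
        raise DomainError("M and S must be positive")
    bmi = np.asarray(bmi, dtype=float)
    if np.any(bmi <= 0):
        raise DomainError("bmi must be positive")
    if L == 0.0:
        out = np.log(bmi / M) / S
    else:
        out = ((bmi / M) ** L - 1.0) / (L * S)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Population generation
# ---------------------------------------------------------------------------


def _draw_valid_z(rng: np.random.Generator, n: int, L: np.ndarray,
                  S: np.ndarray) -> np.ndarray:
    """Standard-normal draws kept inside the Box-Cox domain 1 + L S z > 0.

    Redraws the (vanishingly rare, |z| ~ 6+) out-of-domain deviates so the
    transform is always defined.
    """
    z = rng.standard_normal(n)
    bad = 1.0 + L * S * z <= 0.0
    while np.any(bad):
        z[bad] = rng.standard_normal(int(bad.sum()))
        bad = 1.0 + L * S * z <= 0.0
    return z


def create_population(
    n: int,
    profile: TownProfile,
    bundle: ReferenceBundle,
    seed: int,
    afterschool_fraction: float = DEFAULT_AFTERSCHOOL_FRACTION,
    intake_multiplier_mean: float | None = None,
    intake_multiplier_sd: float | None = None,
) -> list[Agent]:
    """Generate ``n`` agents for a town.

    Draw order (fixed for reproducibility): sex, age, height noise, BMI
    z-score, intake multiplier, after-school attendance.

    * sex ~ Bernoulli(0.511 male); age ~ continuous uniform over [6, 13) y
    * height = reference median height-for-age x (1 + cv x noise)
    * BMI via the LMS transform with the town-adjusted median; weight from
      BMI and height
    * intake multiplier ~ Normal(town mean, sd), truncated to > 0
    * attendance ~ Bernoulli(afterschool_fraction)
    """
    if n < 1:
        raise ConfigurationError("population size must be >= 1")
    if not (0.0 <= afterschool_fraction <= 1.0):
        raise ConfigurationError("afterschool_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)

    male = rng.random(n) < MALE_FRACTION
    age_days = rng.integers(int(6 * 365), int(13 * 365), size=n)
    months = np.asarray(reference.nearest_month(age_days))

    ages_grid, h_per_sex = bundle.height_arrays()
    _, lms_per_sex = bundle.lms_arrays()
    idx = np.searchsorted(ages_grid, months)
    idx = np.clip(idx, 0, len(ages_grid) - 1)

    med_h = np.where(male, h_per_sex["male"]["median_cm"][idx],
                     h_per_sex["female"]["median_cm"][idx])
    cv_h = np.where(male, h_per_sex["male"]["cv"][idx],
                    h_per_sex["female"]["cv"][idx])
    height = med_h * (1.0 + cv_h * rng.standard_normal(n))

    L = np.where(male, lms_per_sex["male"]["L"][idx], lms_per_sex["female"]["L"][idx])
    M = np.where(male, lms_per_sex["male"]["M"][idx], lms_per_sex["female"]["M"][idx])
    S = np.where(male, lms_per_sex["male"]["S"][idx], lms_per_sex["female"]["S"][idx])
    M_town = M + profile.current_population_offset + profile.bmi_median_shift

    z = _draw_valid_z(rng, n, L, S)
    base = 1.0 + L * S * z
    bmi = M_town * base ** (1.0 / L)

    weight = bmi * (height / 100.0) ** 2

    mu = profile.intake_multiplier_mean if intake_multiplier_mean is None \
        else intake_multiplier_mean
    sd = profile.intake_multiplier_sd if intake_multiplier_sd is None \
        else intake_multiplier_sd
    if sd > 0:
        mult = mu + sd * rng.standard_normal(n)
        bad = mult <= 0.0
        while np.any(bad):
            mult[bad] = mu + sd * rng.standard_normal(int(bad.sum()))
            bad = mult <= 0.0
    else:
        mult = np.full(n, mu)

    attends = rng.random(n) < afterschool_fraction

    age_years = age_days / DAYS_PER_YEAR
    rmr = physiology.schofield_rmr_vec(male, age_years, weight, height)

    agents = []
    for i in range(n):
        agents.append(
            Agent(
                id=i,
                sex="male" if male[i] else "female",
                age_days=int(age_days[i]),
                height_cm=float(height[i]),
                weight_kg=float(weight[i]),
                bmi=float(bmi[i]),
                rmr_kcal=float(rmr[i]),
                intake_multiplier=float(mult[i]),
                attends_afterschool=bool(attends[i]),
            )
        )
    return agents


# ---------------------------------------------------------------------------
# Weight-status classification
# ---------------------------------------------------------------------------


def bmi_percentile(agent_bmi: float, age_days: float, sex: str,
                   bundle: ReferenceBundle) -> float:
    """Percentile of a BMI on the reference (town-unshifted) distribution."""
    month = reference.nearest_month(age_days)
    rec = reference.lookup_lms(bundle, int(month), sex)
    z = lms_zscore(rec.L, rec.M, rec.S, agent_bmi)
    return 100.0 * float(stats.norm.cdf(z))


def classify_weight_status(agent: Agent, bundle: ReferenceBundle) -> str:
    """Classify an agent as normal / overweight / obese.

    Thresholds are reference-distribution percentiles: >= 95th obese,
    >= 85th overweight.  The reference is always the unshifted bundle
    median, regardless of the agent's town.
    """
    pct = bmi_percentile(agent.bmi, agent.age_days, agent.sex, bundle)
    if pct >= OBESE_PERCENTILE:
        return "obese"
    if pct >= OVERWEIGHT_PERCENTILE:
        return "overweight"
    return "normal"


def weight_status_fractions(
    bmi: np.ndarray, age_days: np.ndarray, male: np.ndarray,
    bundle: ReferenceBundle,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (overweight-or-more, obese) boolean masks for agent arrays."""
    months = np.asarray(reference.nearest_month(age_days))
    ages_grid, per_sex = bundle.lms_arrays()
    if months.min() < ages_grid[0] or months.max() > ages_grid[-1]:
        bad = int(np.argmax((months < ages_grid[0]) | (months > ages_grid[-1])))
        raise GridRangeError(
            f"agent index {bad}: age {months[bad]} months outside bundle grid"
        )
    idx = np.clip(np.searchsorted(ages_grid, months), 0, len(ages_grid) - 1)
    L = np.where(male, per_sex["male"]["L"][idx], per_sex["female"]["L"][idx])
    M = np.where(male, per_sex["male"]["M"][idx], per_sex["female"]["M"][idx])
    S = np.where(male, per_sex["male"]["S"][idx], per_sex["female"]["S"][idx])
    z = np.empty_like(L)
    zero = L == 0.0
    if np.any(zero):
        z[zero] = np.log(bmi[zero] / M[zero]) / S[zero]
    nz = ~zero
    z[nz] = ((bmi[nz] / M[nz]) ** L[nz] - 1.0) / (L[nz] * S[nz])
    z_over = stats.norm.ppf(OVERWEIGHT_PERCENTILE / 100.0)
    z_obese = stats.norm.ppf(OBESE_PERCENTILE / 100.0)
    return z >= z_over, z >= z_obese


# ---------------------------------------------------------------------------
# Snapshot I/O
# ---------------------------------------------------------------------------

_SNAPSHOT_COLUMNS = [
    "id", "sex", "age_days", "height_cm", "weight_kg", "bmi",
    "intake_multiplier", "attends_afterschool",
]


def population_to_frame(agents: list[Agent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": a.id, "sex": a.sex, "age_days": a.age_days,
                "height_cm": a.height_cm, "weight_kg": a.weight_kg,
                "bmi": a.bmi, "intake_multiplier": a.intake_multiplier,
                "attends_afterschool": a.attends_afterschool,
            }
            for a in agents
        ],
        columns=_SNAPSHOT_COLUMNS,
    )


def write_population(agents: list[Agent], path: str | Path) -> None:
    population_to_frame(agents).to_csv(path, index=False)


def read_population(path: str | Path) -> list[Agent]:
    df = pd.read_csv(path)
    agents = []
    for row in df.itertuples(index=False):
        age_years = row.age_days / DAYS_PER_YEAR
        rmr = physiology.schofield_rmr(row.sex, age_years, row.weight_kg,
                                       row.height_cm)
        agents.append(
            Agent(
                id=int(row.id), sex=row.sex, age_days=int(row.age_days),
                height_cm=float(row.height_cm), weight_kg=float(row.weight_kg),
                bmi=float(row.bmi), rmr_kcal=rmr,
                intake_multiplier=float(row.intake_multiplier),
                attends_afterschool=bool(row.attends_afterschool),
            )
        )
    return agents
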
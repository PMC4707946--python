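"""Simulation loop, RNG management, and output aggregation.

A run proceeds in whole days over a fixed horizon (default 365; every day
is a school day).  Within each day the minute-resolution timeline from
:mod:`kidsim.schedule` determines the agent's PAL; intake and expenditure
are accrued over the day and settled at midnight by the energy-balance
update in :mod:`kidsim.physiology`, followed by reference height growth
and aging.  Daily population summaries mirror the monitors a user of the
interactive model would watch: mean BMI, mean intake, mean daily energy
expenditure, mean calorie surplus, and overweight/obesity percentages by
sex.

All randomness flows from a single seed through a fixed spawn order:
population first, then component enrollments (in fixed component order),
then environment assignment.  Identical configs therefore produce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from types import SimpleNamespace

import numpy as np
import pandas as pd

from . import interventions as iv
from . import physiology, population, reference, schedule
from .errors import ConfigurationError, ConsistencyError, GridRangeError
from .physiology import KCAL_PER_KG
from .population import Agent, TownProfile
from .reference import ReferenceBundle

logger = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Full description of one simulation run."""

    town_type: str = "A"
    n_agents: int = 1000
    n_days: int = 365
    seed: int = 1
    afterschool_fraction: float = population.DEFAULT_AFTERSCHOOL_FRACTION
    #: component_id -> enabled
    components: dict[str, bool] = field(default_factory=dict)
    retention_preset: str = "narrative"
    #: component_id -> {field: value} overrides on the default specs
    overrides: dict[str, dict] = field(default_factory=dict)
    #: bundle file path, or "synthetic:<seed>" for a generated bundle
    bundle: str = "synthetic:1"
    current_population_offset: float = population.DEFAULT_CURRENT_POPULATION_OFFSET
    intake_multiplier_mean: float | None = None
    intake_multiplier_sd: float | None = None
    n_homes: int = 56
    n_schools: int = 12
    n_communities: int = 1
    keep_ledgers: bool = False
    output_dir: str | None = None

    def validate(self) -> None:
        if self.town_type not in reference.TOWN_TYPES:
            raise ConfigurationError(f"unknown town type {self.town_type!r}")
        if self.n_agents < 1:
            raise ConfigurationError("n_agents must be >= 1")
        if self.n_days < 1:
            raise ConfigurationError("n_days must be >= 1")
        if not (0.0 <= self.afterschool_fraction <= 1.0):
            raise ConfigurationError("afterschool_fraction must be in [0, 1]")
        for cid in self.components:
            if cid not in iv.COMPONENT_IDS:
                raise ConfigurationError(f"unknown component {cid!r}")
        for cid in self.overrides:
            if cid not in iv.COMPONENT_IDS:
                raise ConfigurationError(f"unknown component {cid!r} in overrides")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class DailySummary:
    """Population monitors for one simulated day (post-settlement state)."""

    day: int
    mean_bmi: float
    mean_intake_kcal: float
    mean_dee_kcal: float
    mean_calorie_surplus_kcal: float
    pct_overweight_male: float
    pct_overweight_female: float
    pct_obese_male: float
    pct_obese_female: float
    flags: tuple[str, ...] = ()


@dataclass
class SimulationResult:
    config: SimulationConfig
    summaries: list[DailySummary]
    final_population: list[Agent]
    log: list[str]
    ledgers: pd.DataFrame | None = None
    #: ids of agents whose weight was ever clamped at the floor; the exact
    #: conservation identity (final - initial = sum(gaps)/7700) holds for
    #: every agent NOT in this set
    weight_floor_agent_ids: tuple[int, ...] = ()

    def summary_frame(self) -> pd.DataFrame:
        rows = [dataclasses.asdict(s) for s in self.summaries]
        df = pd.DataFrame(rows)
        df["flags"] = df["flags"].map(lambda f: ";".join(f))
        return df

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.summary_frame().to_csv(outdir / "summary.csv", index=False)
        population.write_population(self.final_population,
                                    outdir / "population_final.csv")
        (outdir / "config_echo.json").write_text(
            json.dumps(self.config.to_dict(), indent=1)
        )
        if self.ledgers is not None:
            self.ledgers.to_csv(outdir / "ledgers.csv", index=False)
        (outdir / "run.log").write_text("\n".join(self.log) + "\n")


# ---------------------------------------------------------------------------
# Seed plumbing
# ---------------------------------------------------------------------------


def derive_seeds(seed: int) -> dict[str, int]:
    """Deterministic sub-seeds from the run seed, in documented order."""
    n = 2 + len(iv.COMPONENT_IDS)
    state = np.random.SeedSequence(seed).generate_state(n)
    out = {"population": int(state[0] % (2 ** 31)),
           "environment": int(state[1] % (2 ** 31))}
    for i, cid in enumerate(iv.COMPONENT_IDS):
        out[cid] = int(state[2 + i] % (2 ** 31))
    return out


def resolve_bundle(spec: str) -> ReferenceBundle:
    if spec.startswith("synthetic:"):
        return reference.generate_reference_bundle(int(spec.split(":", 1)[1]))
    return reference.load_bundle(spec)


def resolve_specs(config: SimulationConfig) -> list[iv.InterventionSpec]:
    """Enabled component specs with config overrides applied."""
    specs = []
    for spec in iv.default_specs(config.retention_preset):
        if not config.components.get(spec.component_id, False):
            continue
        ov = config.overrides.get(spec.component_id, {})
        specs.append(iv.with_overrides(spec, **ov) if ov else spec)
    return specs


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


def _summarize_arrays(day, bmi, age_days, male, intake, tee, gap,
                      bundle) -> DailySummary:
    over, obese = population.weight_status_fractions(bmi, age_days, male, bundle)
    band = over & ~obese  # overweight category excludes obese
    flags = []

    def pct(mask, sex_mask, label):
        n = int(sex_mask.sum())
        if n == 0:
            flags.append(f"no-{label}-agents")
            return 0.0
        return 100.0 * float((mask & sex_mask).sum()) / n

    return DailySummary(
        day=int(day),
        mean_bmi=float(bmi.mean()),
        mean_intake_kcal=float(intake.mean()),
        mean_dee_kcal=float(tee.mean()),
        mean_calorie_surplus_kcal=float(gap.mean()),
        pct_overweight_male=pct(band, male, "male"),
        pct_overweight_female=pct(band, ~male, "female"),
        pct_obese_male=pct(obese, male, "male"),
        pct_obese_female=pct(obese, ~male, "female"),
        flags=tuple(dict.fromkeys(flags)),
    )


def summarize_day(agents: list[Agent], ledgers: list[physiology.DailyLedger],
                  bundle: ReferenceBundle) -> DailySummary:
    """Summarize one day from agent state plus that day's ledgers."""
    by_id = {led.agent_id: led for led in ledgers}
    missing = [a.id for a in agents if a.id not in by_id]
    if missing:
        raise ConsistencyError(f"missing ledger rows for agents {missing[:5]}")
    day = ledgers[0].day
    bmi = np.array([a.bmi for a in agents])
    age_days = np.array([a.age_days for a in agents])
    male = np.array([a.sex == "male" for a in agents])
    intake = np.array([by_id[a.id].intake_kcal for a in agents])
    tee = np.array([by_id[a.id].expenditure_kcal for a in agents])
    gap = np.array([by_id[a.id].calorie_gap_kcal for a in agents])
    return _summarize_arrays(day, bmi, age_days, male, intake, tee, gap, bundle)


# ---------------------------------------------------------------------------
# The run loop
# ---------------------------------------------------------------------------

_ACTIVITY_BITS = {cid: 1 << i for i, cid in enumerate(iv.ACTIVITY_COMPONENTS)}
_ATTENDS_BIT = 1 << len(iv.ACTIVITY_COMPONENTS)


def _pal_for_key(key: int, profile: TownProfile, bundle: ReferenceBundle,
                 specs_by_id: dict) -> float:
    attends = bool(key & _ATTENDS_BIT)
    active = [
        specs_by_id[cid] for cid, bit in _ACTIVITY_BITS.items()
        if key & bit and cid in specs_by_id
    ]
    dummy = SimpleNamespace(attends_afterschool=attends)
    tl = schedule.build_day_timeline(dummy, profile, bundle, active)
    return tl.pal()


def run_simulation(config: SimulationConfig,
                   bundle: ReferenceBundle | None = None) -> SimulationResult:
    """Run one simulation and return its result.

    Raises :class:`ConfigurationError` before any simulation work if the
    config is invalid, and :class:`GridRangeError` naming the first
    offending agent if aging walks off the reference grid mid-run.
    """
    config.validate()
    if bundle is None:
        bundle = resolve_bundle(config.bundle)
    seeds = derive_seeds(config.seed)
    log = [
        f"config_hash={_hash_dict(config.to_dict())}",
        f"bundle_hash={_hash_dict(bundle.to_dict())}",
        f"seed={config.seed}",
    ]

    profile = TownProfile.from_bundle(
        config.town_type, bundle,
        current_population_offset=config.current_population_offset,
    )
    agents = population.create_population(
        config.n_agents, profile, bundle, seeds["population"],
        afterschool_fraction=config.afterschool_fraction,
        intake_multiplier_mean=config.intake_multiplier_mean,
        intake_multiplier_sd=config.intake_multiplier_sd,
    )
    env = schedule.Environment(config.n_homes, config.n_schools,
                               config.n_communities)
    env.assign([a.id for a in agents], seeds["environment"])

    specs = resolve_specs(config)
    specs_by_id = {s.component_id: s for s in specs}
    n = len(agents)
    enrolled = {}
    dropout = {}
    for spec in specs:
        enr = iv.assign_enrollment(agents, spec, seeds[spec.component_id],
                                   n_days=config.n_days)
        e = np.zeros(n, dtype=bool)
        d = np.zeros(n, dtype=np.int64)  # 0 = retained all year
        for rec in enr:
            e[rec.agent_id] = rec.enrolled
            if rec.dropout_day is not None:
                d[rec.agent_id] = rec.dropout_day
            if rec.enrolled:
                agents[rec.agent_id].enrollments[spec.component_id] = rec.dropout_day
        enrolled[spec.component_id] = e
        dropout[spec.component_id] = d
        log.append(
            f"component {spec.component_id}: enrolled {int(e.sum())}/{n}"
        )

    # struct-of-arrays mirror of the agent list
    male = np.array([a.sex == "male" for a in agents])
    age_days = np.array([a.age_days for a in agents], dtype=np.int64)
    height = np.array([a.height_cm for a in agents])
    weight = np.array([a.weight_kg for a in agents])
    mult = np.array([a.intake_multiplier for a in agents])
    attends = np.array([a.attends_afterschool for a in agents])

    vel_ages, vel_per_sex = bundle.velocity_arrays()
    pal_cache: dict[int, float] = {}
    dietary = [s for s in specs if s.dose_kcal is not None]
    activity_ids = [c for c in iv.ACTIVITY_COMPONENTS if c in specs_by_id]

    summaries: list[DailySummary] = []
    ledger_rows = [] if config.keep_ledgers else None
    floor_hits = 0
    floored = np.zeros(n, dtype=bool)

    base_key = attends.astype(np.int64) * _ATTENDS_BIT
    for day in range(1, config.n_days + 1):
        keys = base_key.copy()
        for cid in activity_ids:
            active = enrolled[cid] & ((dropout[cid] == 0) | (day < dropout[cid]))
            keys += active.astype(np.int64) * _ACTIVITY_BITS[cid]
        uniq, inverse = np.unique(keys, return_inverse=True)
        pal_u = np.empty(len(uniq))
        for j, k in enumerate(uniq):
            k = int(k)
            if k not in pal_cache:
                pal_cache[k] = _pal_for_key(k, profile, bundle, specs_by_id)
            pal_u[j] = pal_cache[k]
        pal = pal_u[inverse]

        adj = np.zeros(n)
        for spec in dietary:
            active = (enrolled[spec.component_id]
                      & ((dropout[spec.component_id] == 0)
                         | (day < dropout[spec.component_id])))
            adj += np.where(active & attends, spec.dose_kcal, 0.0)

        rmr = physiology.schofield_rmr_vec(
            male, age_days / population.DAYS_PER_YEAR, weight, height
        )
        intake = np.maximum(rmr * mult + adj, 0.0)
        tee = rmr * pal
        gap = intake - tee

        if ledger_rows is not None:
            for i in range(n):
                ledger_rows.append(
                    (agents[i].id, day, intake[i], tee[i], gap[i], pal[i])
                )

        # midnight settlement: energy balance, then growth and aging
        weight = weight + gap / KCAL_PER_KG
        low = weight < physiology.MIN_WEIGHT_KG
        if np.any(low):
            floor_hits += int(low.sum())
            floored |= low
            logger.warning("weight floor hit by %d agents on day %d",
                           int(low.sum()), day)
            weight[low] = physiology.MIN_WEIGHT_KG

        months = np.asarray(reference.nearest_month(age_days))
        if months.max() > vel_ages[-1] or months.min() < vel_ages[0]:
            bad = int(np.argmax((months > vel_ages[-1]) | (months < vel_ages[0])))
            raise GridRangeError(
                f"agent {agents[bad].id} aged to {months[bad]} months, "
                f"outside the bundle grid"
            )
        idx = months - int(vel_ages[0])
        vel = np.where(male, vel_per_sex["male"][idx], vel_per_sex["female"][idx])
        height = height + vel
        age_days = age_days + 1
        bmi = weight / (height / 100.0) ** 2

        summaries.append(
            _summarize_arrays(day, bmi, age_days, male, intake, tee, gap, bundle)
        )

    # write final state back onto the agent objects
    rmr = physiology.schofield_rmr_vec(
        male, age_days / population.DAYS_PER_YEAR, weight, height
    )
    for i, a in enumerate(agents):
        a.age_days = int(age_days[i])
        a.height_cm = float(height[i])
        a.weight_kg = float(weight[i])
        a.bmi = float(weight[i] / (height[i] / 100.0) ** 2)
        a.rmr_kcal = float(rmr[i])

    log.append(f"days={config.n_days} agents={n} weight_floor_hits={floor_hits}")
    log.append(f"final_mean_bmi={summaries[-1].mean_bmi:.4f}")

    ledgers = None
    if ledger_rows is not None:
        ledgers = pd.DataFrame(
            ledger_rows,
            columns=["agent_id", "day", "intake_kcal", "expenditure_kcal",
                     "calorie_gap_kcal", "pal"],
        )
    result = SimulationResult(
        config=config, summaries=summaries, final_population=agents, log=log,
        ledgers=ledgers,
        weight_floor_agent_ids=tuple(int(agents[i].id)
                                     for i in np.flatnonzero(floored)),
    )
    if config.output_dir is not None:
        result.write(config.output_dir)
    return result


def _hash_dict(d: dict) -> str:
    return hashlib.sha256(
        json.dumps(d, sort_keys=True).encode()
    ).hexdigest()[:12]
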
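# Methods

## Model overview

`kidsim` is a discrete-time, individual-based model of energy balance in
children aged 6–12. Each agent carries sex, age (in days), height,
weight, an intake multiplier, an after-school attendance flag, and
intervention enrollments. Days are identical school days; within a day
the agent's minute-resolution activity timeline determines a physical
activity level (PAL), and at midnight the day's calorie gap is settled
into weight at 7,700 kcal/kg, followed by reference height growth and
aging. Population outcomes (mean BMI, obesity prevalence by sex) emerge
from aggregation.

Key structural assumptions:

- **Energy model.** Intake and expenditure are both proportional to the
  Schofield resting metabolic rate. Expenditure: TEE = RMR × PAL.
  Intake: RMR × multiplier (+ dietary intervention decrements, floored
  at zero). The multiplier is a fixed agent property drawn at
  initialization; only intervention adjustments vary day to day.
- **Growth.** Height follows the reference velocity for the agent's
  current (age, sex) and is uncoupled from energy balance; weight
  responds only to the calorie gap. No adaptive thermogenesis, no
  body-composition partitioning.
- **Schedule.** 00:00–08:00 home, 08:00–15:00 school, 15:00–19:00
  community for the attending fraction (default 15%) and home for the
  rest, 19:00–24:00 home. Sleep is 600 minutes at MET 1.0 (21:00–07:00);
  all unassigned awake time is sedentary at MET 1.5. Every day of the
  365-day horizon is a school day (an academic calendar and
  weekday/weekend contrasts are possible refinements, not modeled).
- **No agent interaction.** Agents share environments but do not
  influence one another; there is no behavioral spillover mechanism.

## Parameters

| Parameter | Default | Units | Notes |
|---|---|---|---|
| kcal per kg weight change | 7,700 | kcal/kg | energy-balance constant |
| Schofield bands | 4 printed equations | kcal/day | boundary at age 10 → older band (configurable convention) |
| sex ratio | 51.1% boys | — | census-style default |
| age at init | uniform [6, 13) y | days | every integer age 6–12 equally likely |
| intake multiplier | N(1.6, 0.1), truncated > 0 | ×RMR | towns A and B; town C mean exactly 0.01 lower |
| after-school attendance | 15% | — | Bernoulli per agent, same across towns |
| sleep | 600 min @ MET 1.0 | — | fixed |
| sedentary filler | MET 1.5 | — | fixed |
| town B BMI shift | +0.5 | kg/m² | exact at every (age, sex) |
| town A current-population offset | +1.0 | kg/m² | configurable; town C uses the reference median (offset 0) |
| overweight / obese cut points | 85th / 95th reference percentile | — | children's convention |
| weight floor | 10 | kg | guard against pathological configs; logged and tracked per agent |
| school programs (dose, reach) | 40′@2.99 (10%), 10′@2.62 (90%), 30′@4.96 (75%) | min @ MET | programs 1–3 |
| school program retention | 80/80/90% (`narrative`) or 80/90/80% (`tabular`) | — | two documented presets; sources disagree, neither is silently preferred |
| OST components | −60 kcal, 15′@4.5, −68.25 kcal | — | reach 15%, retention 80% each |
| MVPA reporting cut points | 6.0 (school programs), 4.5 (OST) | MET | reporting only, no dynamics |
| environment | 56 homes, 12 schools, 1 community | — | stylized, no dynamics; community count configurable (a 3-community variant appears in some descriptions) |

Intervention semantics: *reach* is Bernoulli enrollment over the
eligible population (everyone for school programs; attendees only for
OST components). *Retention* is end-of-year survival: each enrollee
drops out with probability 1 − retention at a day uniform on [1, 365].
The uniform dropout day is the smoothest assumption consistent with an
end-of-year definition; "drop at day 1"/"drop at day 365" extremes are
available by overriding dropout handling for sensitivity analysis.
Activity bouts *replace* sedentary minutes inside their program window
(morning home hour for the before-school program, school hours for the
classroom and walking programs, community hours for the OST bout) —
replacement is the only reading that keeps the day at 1440 minutes. A
bout larger than the window's sedentary reserve is truncated with a
logged warning. Dietary doses apply only on days the agent attends the
community program, and stack additively.

## Synthetic reference bundles

The model's real-world analogues are parameterized from growth charts
and national survey data; those inputs are not redistributable here, so
`kidsim.reference` generates synthetic bundles that emulate their
**structure**: a complete monthly (age, sex) grid of LMS records
(Box–Cox L, median M, coefficient of variation S), median
height-for-age with a cv, growth velocities, and per-town activity
patterns. The curves are smooth quadratics in age with small seeded
jitter on their coefficients; M is strictly increasing in age and
velocities are the analytic derivative of the height median, so
integrated growth tracks the reference exactly. The grid spans 72–216
months so agents initialized just under age 13 can age through long
runs. A user can substitute a real bundle in the same JSON/YAML format
(a `version` field is required).

What the synthetic bundle does **not** emulate: the true shapes of
growth-chart L/M/S curves (pubertal inflections in particular),
height–BMI correlation at initialization (drawn independently by
default), race/ethnicity and socioeconomic structure, and day-of-week
or seasonal activity variation. Passing tests therefore demonstrate the
*mechanics* of the model — transforms, accounting, scheduling,
intervention logic — not calibration to any real population.

## Town quantification

The three towns differ in (a) initialization BMI median, (b) activity
pattern, (c) intake multiplier. The town contrasts for activity are
qualitative in origin ("no in-school physical education", "more after
school"); the bundle defaults quantify them as: town A — 15′@3.0 before
school, 90′@5.0 in school, 45′@4.0 in community, 30′@3.0 in the
evening; town B — same but 0 elevated minutes in school; town C — same
as A with 75′@4.0 in community. These are assumptions, clearly
overridable in the bundle file.

The town-A defaults give a baseline PAL of ≈1.56 for a non-attendee
against an intake multiplier of 1.6, i.e. a small positive mean calorie
surplus (≈40–55 kcal/day). This is deliberate: an "average obesity
rates" town should drift slowly upward, and with the +1.0 kg/m²
current-population offset it holds obesity prevalence near 15–17% over
a simulated year, a realistic level for such a town.

## Numerical choices

- **RNG.** One run seed feeds a `SeedSequence`; sub-seeds are drawn in
  a fixed documented order (population, environment, then components in
  fixed order). Runs are byte-reproducible; identical configs produce
  identical output files.
- **LMS domain.** Draws with 1 + LSz ≤ 0 (probability ~10⁻⁹ at the
  default parameters) are redrawn. The inverse transform is closed-form
  and round-trips to 1e−9 over the realistic parameter range.
- **Nearest-age lookup.** Reference lookups use the nearest grid month,
  ties to the younger month (30.4375 days/month). Interpolation between
  chart ages is not used — a convention, not a claim about the source
  references.
- **Age-10 band boundary.** Exact age 10 uses the older Schofield band;
  the bands are intentionally discontinuous there, matching their
  printed form.
- **Weight floor.** 10 kg. An agent in the extreme joint tail (low
  multiplier × small body) loses weight indefinitely under this energy
  model because RMR retains a positive intercept; the floor clamps such
  trajectories, logs a warning, and records the agent id so conservation
  audits can exclude exactly those agents.
- **Accounting.** The conservation identity final − initial weight =
  Σ(daily gaps)/7,700 holds to better than 1e−6 kg for every unfloored
  agent over a 365-day run. Hourly records are analytic aggregates of
  the minute timeline (hour h expends RMR·Σmet/1440) and sum exactly to
  daily totals; intake is booked in three equal meal ticks (07:00,
  12:00, 19:00).
- **Performance.** The engine runs on struct-of-arrays with a per-day
  cache of distinct (attendance × active-bout) timelines, of which there
  are at most 32; a 365-day, 5,000-agent run takes ~1 s on one CPU.
  Tests and the acceptance script use 1,000–10,000 agents — sizes at
  which binomial checks at 3 standard errors are meaningful.

## Known limitations

- The intake-on-RMR relationship is a configured multiplier, not an
  estimated regression; its default (1.6) and spread (0.1) are
  conventional values, and the spread's right tail produces the floor
  pathology above at population scale.
- Single-year horizon semantics: retention is defined against day 365;
  longer runs reuse the same enrollment without re-enrollment waves.
- Outputs classify weight status against the synthetic reference;
  absolute prevalence numbers are only meaningful relative to that
  reference, not to any national chart.
- The interactive affordances of the original modeling environment
  (live animation, sliders) are out of scope; the CLI and CSV outputs
  are the interface.
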
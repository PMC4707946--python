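# kidsim

An agent-based simulation of childhood BMI dynamics for evaluating
school- and community-based obesity-prevention interventions.

Simulated children aged 6–12 live in one of three stylized town types,
move daily between home, school, and an after-school community program,
accumulate caloric intake and MET-weighted energy expenditure, and grow
in height and weight over a 365-day year. Two multi-component
interventions can be switched on: three school physical-activity
programs (a before-school program, a classroom program, and a
walking/running program) and three out-of-school-time components
(beverage substitution, added activity, snack substitution), each
parameterized by dose, reach, and retention.

The package is intended for intervention modelers and public-health
methodologists who want a reproducible, scriptable implementation of
this class of model: every run is deterministic given its seed, all
reference inputs travel in a single documented bundle file, and outputs
are plain CSV/JSON.

## The model

For each agent with weight *W* (kg), height *H* (cm), age, and sex:

- **Resting metabolic rate** (kcal/day) from the Schofield equations,
  e.g. boys 3–10 y: RMR = 19.59 *W* + 1.303 *H* + 414.9; girls 10–18 y:
  RMR = 8.365 *W* + 4.65 *H* + 200.0 (four age/sex bands; the band
  boundary at exactly age 10 goes to the older band).
- **Physical activity level** PAL = (Σ per-minute METs)/1440 over the
  day's minute-resolution timeline (sleep 600 min at MET 1.0, sedentary
  filler at MET 1.5, town-specific activity blocks, intervention bouts
  replacing sedentary minutes).
- **Expenditure** TEE = RMR × PAL; **intake** = RMR × *m* + Δ, where *m*
  is an agent-level intake multiplier and Δ the active dietary
  intervention decrement.
- **Energy balance**: the daily calorie gap (intake − TEE) converts to
  weight change at 7,700 kcal per kilogram, settled at midnight. Height
  grows at an age/sex-conditional reference velocity, uncoupled from
  behavior; BMI = *W*/(H/100)².
- **Initialization**: BMI is drawn through the LMS (Box–Cox) transform
  BMI = M(1 + LSz)^{1/L} with age/sex-specific L, M, S from the
  reference bundle; town C uses the reference median M, town A adds a
  current-population offset, town B sits exactly +0.5 kg/m² above A.
  Weight status is classified against the unshifted reference (≥85th
  percentile overweight, ≥95th obese).

Real growth-chart/survey reference data are not bundled; a synthetic
reference generator (`kidsim.reference`) emulates their structure so the
whole model is testable offline. See `docs/methods.md` for assumptions
and limitations.

## Worked example

```sh
kidsim run --town A --n-agents 2000 --days 365 --seed 7 --hkos --out out/demo
```

prints

```
day 365: mean BMI 16.99 kg/m^2, mean intake 1893 kcal, mean DEE 1851 kcal, mean surplus 42 kcal
obese: 15.5% of boys, 16.8% of girls -> outputs in out/demo
```

i.e. after one simulated year in the average town with all three
out-of-school-time components on, the population's mean BMI is
16.99 kg/m², the mean child eats 1893 kcal/day against 1851 kcal/day of
expenditure (a 42 kcal/day mean surplus — a slowly rising population),
and about 16% of children are obese. The same run without `--hkos` ends
at mean BMI 17.08 kg/m² and a 45 kcal/day surplus: the components reach
only 15% of the 15% of children attending the after-school program, so
the population-mean effect is small but strictly negative, as expected.

`out/demo/` contains `summary.csv` (one row per day: mean BMI, intake,
DEE, surplus, and overweight/obese percentages by sex), the final
population snapshot, a config echo, and the run log. The same run is
available from Python:

```python
from kidsim import SimulationConfig, run_simulation
res = run_simulation(SimulationConfig(town_type="A", n_agents=2000,
                                      seed=7, components={"DrinkRight": True,
                                      "MoveMore": True, "SnackSmart": True}))
print(res.summaries[-1].mean_bmi)
```

Other subcommands: `kidsim make-bundle` (write a synthetic reference
bundle), `kidsim sweep` (grid of configs), `kidsim dump-timeline`
(minute/context/MET debug dump of one agent-day).

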
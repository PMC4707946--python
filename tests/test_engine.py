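"""Simulation loop: determinism, equilibrium, accounting, summaries, CLI."""

import filecmp
from types import SimpleNamespace

import numpy as np
import pytest

from kidsim import engine, physiology, schedule
from kidsim.engine import (
    DailySummary,
    SimulationConfig,
    run_simulation,
    summarize_day,
)
from kidsim.errors import ConfigurationError, ConsistencyError
from kidsim.physiology import DailyLedger
from kidsim.population import Agent, TownProfile


def baseline_pal(bundle, town="A", attends=False):
    profile = TownProfile.from_bundle(town, bundle)
    dummy = SimpleNamespace(attends_afterschool=attends)
    return schedule.build_day_timeline(dummy, profile, bundle).pal()


class TestRunSimulation:
    def test_forced_equilibrium(self, bundle):
        """With the intake multiplier pinned to the day's PAL, intake equals
        expenditure: zero surplus and zero weight change for every agent."""
        pal = baseline_pal(bundle)
        cfg = SimulationConfig(
            town_type="A", n_agents=100, n_days=1, seed=5,
            afterschool_fraction=0.0,
            intake_multiplier_mean=pal, intake_multiplier_sd=0.0,
            keep_ledgers=True,
        )
        res = run_simulation(cfg, bundle=bundle)
        assert res.summaries[0].mean_calorie_surplus_kcal == 0.0
        assert np.all(res.ledgers["calorie_gap_kcal"].to_numpy() == 0.0)

    def test_identical_configs_give_byte_identical_outputs(self, tmp_path):
        out1, out2 = tmp_path / "r1", tmp_path / "r2"
        for out in (out1, out2):
            cfg = SimulationConfig(town_type="B", n_agents=150, n_days=20,
                                   seed=42, components={"ASAP3": True},
                                   output_dir=str(out))
            run_simulation(cfg)
        for name in ("summary.csv", "population_final.csv"):
            assert filecmp.cmp(out1 / name, out2 / name, shallow=False)

    def test_invalid_config_fails_before_any_work(self):
        with pytest.raises(ConfigurationError):
            run_simulation(SimulationConfig(n_agents=0))
        with pytest.raises(ConfigurationError):
            run_simulation(SimulationConfig(town_type="Z"))
        with pytest.raises(ConfigurationError):
            run_simulation(SimulationConfig(components={"ASAP9": True}))

    def test_tick_accounting_matches_ledger(self, bundle):
        """Hourly expenditure/intake records sum to the daily ledger totals."""
        cfg = SimulationConfig(n_agents=20, n_days=1, seed=8,
                               keep_ledgers=True)
        res = run_simulation(cfg, bundle=bundle)
        profile = TownProfile.from_bundle("A", bundle)
        for agent, row in zip(res.final_population,
                              res.ledgers.itertuples(index=False)):
            tl = schedule.build_day_timeline(agent, profile, bundle)
            rmr = row.expenditure_kcal / row.pal
            hours = physiology.hourly_expenditure(tl.mets, rmr)
            assert hours.sum() == pytest.approx(row.expenditure_kcal, abs=1e-8)
            assert physiology.hourly_intake(row.intake_kcal).sum() == \
                pytest.approx(row.intake_kcal, abs=1e-9)

    def test_conservation_short_run(self, bundle):
        cfg = SimulationConfig(n_agents=300, n_days=60, seed=17,
                               keep_ledgers=True)
        res = run_simulation(cfg, bundle=bundle)
        start = engine.population.create_population(
            300, TownProfile.from_bundle("A", bundle), bundle,
            engine.derive_seeds(17)["population"],
        )
        gaps = res.ledgers.groupby("agent_id")["calorie_gap_kcal"].sum()
        floored = set(res.weight_floor_agent_ids)
        for a0, a1 in zip(start, res.final_population):
            if a1.id in floored:
                continue
            assert a1.weight_kg - a0.weight_kg == pytest.approx(
                gaps[a1.id] / physiology.KCAL_PER_KG, abs=1e-6
            )

    def test_scaling_stability(self, bundle):
        """Doubling the population barely moves the final mean BMI."""
        def final_bmi_stats(n):
            cfg = SimulationConfig(n_agents=n, n_days=30, seed=23)
            res = run_simulation(cfg, bundle=bundle)
            bmis = np.array([a.bmi for a in res.final_population])
            return bmis.mean(), bmis.std(ddof=1) / np.sqrt(n)

        m1, se1 = final_bmi_stats(1500)
        m2, _ = final_bmi_stats(3000)
        assert abs(m2 - m1) < 3 * se1


class TestSummarizeDay:
    def _agent(self, i, sex="female"):
        return Agent(id=i, sex=sex, age_days=3000, height_cm=130.0,
                     weight_kg=28.0, bmi=28.0 / 1.3**2, rmr_kcal=1100.0,
                     intake_multiplier=1.6, attends_afterschool=False)

    def _ledger(self, i, intake=1600.0, tee=1500.0):
        return DailyLedger(agent_id=i, day=1, intake_kcal=intake,
                           expenditure_kcal=tee,
                           calorie_gap_kcal=intake - tee, pal=1.4,
                           contexts=[("home", 1440, 1.5)])

    def test_single_agent_surplus(self, bundle):
        s = summarize_day([self._agent(0)], [self._ledger(0)], bundle)
        assert s.mean_calorie_surplus_kcal == pytest.approx(100.0)
        assert s.mean_intake_kcal == 1600.0
        assert s.mean_dee_kcal == 1500.0

    def test_all_female_population_flags_empty_male_stratum(self, bundle):
        agents = [self._agent(i) for i in range(3)]
        ledgers = [self._ledger(i) for i in range(3)]
        s = summarize_day(agents, ledgers, bundle)
        assert s.pct_obese_male == 0.0
        assert "no-male-agents" in s.flags

    def test_missing_ledger_is_consistency_error(self, bundle):
        agents = [self._agent(0), self._agent(1)]
        with pytest.raises(ConsistencyError):
            summarize_day(agents, [self._ledger(0)], bundle)

    def test_percentages_bounded(self, bundle):
        cfg = SimulationConfig(n_agents=400, n_days=3, seed=31)
        res = run_simulation(cfg, bundle=bundle)
        for s in res.summaries:
            for v in (s.pct_overweight_male, s.pct_overweight_female,
                      s.pct_obese_male, s.pct_obese_female):
                assert 0.0 <= v <= 100.0
            assert s.mean_calorie_surplus_kcal == pytest.approx(
                s.mean_intake_kcal - s.mean_dee_kcal, abs=1e-9
            )


class TestCLI:
    def test_run_and_make_bundle(self, tmp_path):
        from click.testing import CliRunner
        from kidsim.cli import main

        runner = CliRunner()
        bpath = tmp_path / "bundle.json"
        r = runner.invoke(main, ["make-bundle", "--seed", "3",
                                 "--out", str(bpath)])
        assert r.exit_code == 0, r.output
        out = tmp_path / "run"
        r = runner.invoke(main, [
            "run", "--town", "A", "--n-agents", "30", "--days", "2",
            "--seed", "4", "--hkos", "--bundle", str(bpath),
            "--out", str(out),
        ])
        assert r.exit_code == 0, r.output
        assert (out / "summary.csv").exists()
        assert (out / "config_echo.json").exists()
        assert (out / "population_final.csv").exists()
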
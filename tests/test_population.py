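"""LMS transform, population generation, and weight-status classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from kidsim import population, reference
from kidsim.errors import ConfigurationError, DomainError
from kidsim.population import (
    TownProfile,
    bmi_percentile,
    classify_weight_status,
    create_population,
    lms_quantile,
    lms_zscore,
    weight_status_fractions,
)


class TestLMSQuantile:
    def test_z_zero_returns_median(self):
        for L in (-2.0, -1.0, 0.0, 1.0, 2.5):
            assert lms_quantile(L, 17.0, 0.12, 0.0) == pytest.approx(17.0, abs=0)

    def test_l_one_reduces_to_linear(self):
        assert lms_quantile(1.0, 17.0, 0.10, 1.0) == pytest.approx(18.7)

    def test_matches_monte_carlo_95th_percentile(self):
        """Closed-form z=1.645 quantile agrees with a brute-force sampling
        oracle pushing 10^6 standard-normal draws through the transform."""
        L, M, S = -1.5, 17.0, 0.12
        rng = np.random.default_rng(2024)
        z = rng.standard_normal(10**6)
        z = z[1.0 + L * S * z > 0.0]
        sample_q95 = np.quantile(lms_quantile(L, M, S, z), 0.95)
        assert lms_quantile(L, M, S, 1.645) == pytest.approx(sample_q95, rel=2e-3)

    def test_domain_error_outside_boxcox_range(self):
        with pytest.raises(DomainError):
            lms_quantile(-1.5, 17.0, 0.12, 10.0)
        with pytest.raises(DomainError):
            lms_quantile(1.0, -17.0, 0.12, 0.0)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    L=st.one_of(st.just(0.0), st.floats(-3.0, -1e-3), st.floats(1e-3, 3.0)),
    M=st.floats(10.0, 35.0),
    S=st.floats(0.02, 0.25),
    z=st.floats(-4.0, 4.0),
)
def test_lms_inversion_round_trip(L, M, S, z):
    """z-score of the z-quantile returns z to within 1e-9.

    L is either exactly zero (log form) or bounded away from zero;
    growth references use L well inside this range.
    """
    if L != 0.0 and 1.0 + L * S * z <= 1e-6:
        return
    bmi = lms_quantile(L, M, S, z)
    assert lms_zscore(L, M, S, bmi) == pytest.approx(z, abs=1e-9)


class TestCreatePopulation:
    def test_composition_at_scale(self, profile_a, bundle):
        agents = create_population(10_000, profile_a, bundle, seed=7)
        male_frac = np.mean([a.sex == "male" for a in agents])
        se = np.sqrt(0.511 * 0.489 / 10_000)
        assert abs(male_frac - 0.511) < 3 * se
        att = np.mean([a.attends_afterschool for a in agents])
        se = np.sqrt(0.15 * 0.85 / 10_000)
        assert abs(att - 0.15) < 3 * se

    def test_age_range_and_bmi_identity(self, profile_a, bundle):
        agents = create_population(500, profile_a, bundle, seed=3)
        for a in agents:
            assert 6 * 365 <= a.age_days <= 13 * 365
            assert a.bmi == pytest.approx(
                a.weight_kg / (a.height_cm / 100.0) ** 2, rel=1e-12
            )
            assert a.rmr_kcal > 0
            assert a.intake_multiplier > 0

    def test_seeded_determinism(self, profile_a, bundle):
        a1 = create_population(200, profile_a, bundle, seed=11)
        a2 = create_population(200, profile_a, bundle, seed=11)
        assert a1 == a2

    def test_rejects_empty_population(self, profile_a, bundle):
        with pytest.raises(ConfigurationError):
            create_population(0, profile_a, bundle, seed=1)

    def test_town_mean_bmi_ordering_at_init(self, bundle, profile_a, profile_b,
                                            profile_c):
        means = {}
        for prof in (profile_a, profile_b, profile_c):
            agents = create_population(10_000, prof, bundle, seed=5)
            means[prof.town_type] = np.mean([a.bmi for a in agents])
        assert means["C"] < means["A"] < means["B"]


class TestTownProfile:
    def test_b_minus_a_shift_is_half_unit(self, profile_a, profile_b):
        assert profile_b.bmi_median_shift - profile_a.bmi_median_shift == 0.5

    def test_town_c_uses_reference_median(self, profile_c, bundle):
        rec = reference.lookup_lms(bundle, 100, "female")
        assert profile_c.median_bmi(bundle, 100, "female") == rec.M

    def test_unknown_town_rejected(self, bundle):
        with pytest.raises(ConfigurationError):
            TownProfile.from_bundle("D", bundle)


class TestClassifyWeightStatus:
    def _agent_at_z(self, bundle, z, sex="male", age_days=3000):
        month = reference.nearest_month(age_days)
        rec = reference.lookup_lms(bundle, month, sex)
        bmi = lms_quantile(rec.L, rec.M, rec.S, z)
        return population.Agent(
            id=0, sex=sex, age_days=age_days, height_cm=130.0,
            weight_kg=bmi * 1.69, bmi=bmi, rmr_kcal=1000.0,
            intake_multiplier=1.6, attends_afterschool=False,
        )

    def test_reference_median_is_normal(self, bundle):
        agent = self._agent_at_z(bundle, 0.0)
        assert classify_weight_status(agent, bundle) == "normal"

    def test_97th_percentile_is_obese(self, bundle):
        agent = self._agent_at_z(bundle, stats.norm.ppf(0.97))
        assert classify_weight_status(agent, bundle) == "obese"

    def test_90th_percentile_is_overweight(self, bundle):
        agent = self._agent_at_z(bundle, stats.norm.ppf(0.90))
        assert classify_weight_status(agent, bundle) == "overweight"

    def test_percentile_inverts_quantile(self, bundle):
        agent = self._agent_at_z(bundle, 1.0)
        pct = bmi_percentile(agent.bmi, agent.age_days, agent.sex, bundle)
        assert pct == pytest.approx(100 * stats.norm.cdf(1.0), abs=1e-9)

    def test_reference_draws_give_five_percent_obese(self, bundle):
        """Sampling oracle: agents drawn from the unshifted reference are
        obese (>= 95th percentile) about 5% of the time."""
        n = 10**6
        rng = np.random.default_rng(99)
        rec = reference.lookup_lms(bundle, 120, "female")
        z = rng.standard_normal(n)
        z = z[1.0 + rec.L * rec.S * z > 0.0]
        bmi = lms_quantile(rec.L, rec.M, rec.S, z)
        age = np.full(len(bmi), 120 * reference.DAYS_PER_MONTH)
        male = np.zeros(len(bmi), dtype=bool)
        _, obese = weight_status_fractions(bmi, age, male, bundle)
        se = np.sqrt(0.05 * 0.95 / len(bmi))
        assert abs(obese.mean() - 0.05) < 4 * se


def test_snapshot_round_trip(profile_a, bundle, tmp_path):
    agents = create_population(50, profile_a, bundle, seed=2)
    path = tmp_path / "pop.csv"
    population.write_population(agents, path)
    back = population.read_population(path)
    for a, b in zip(agents, back):
        assert a.id == b.id and a.sex == b.sex
        assert a.bmi == pytest.approx(b.bmi, rel=1e-12)
        assert a.attends_afterschool == b.attends_afterschool
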
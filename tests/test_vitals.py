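"""Vital-rate construction: Kaplan-Meier, the age-size map, the survival
and fecundity regressions and the growth-residual spread."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

import medaka_ipm as m

from conftest import make_draws


def records(exit_days, events, entry=60):
    n = len(exit_days)
    return pd.DataFrame(
        {
            "fish_id": [f"f{i}" for i in range(n)],
            "tank_id": "t1",
            "treatment_temp": "warm",
            "treatment_food": "continuous",
            "entry_day": entry,
            "exit_day": exit_days,
            "event": events,
        }
    )


class TestKaplanMeier:
    def test_hand_product_limit(self):
        # 5 fish, deaths at 61 and 63: S = (4/5), then (4/5)(3/4) = 0.6
        rec = records([61, 63, 350, 350, 350], ["death", "death"] + ["censored"] * 3)
        km = m.kaplan_meier(rec)
        assert km.evaluate(61)[0] == pytest.approx(0.8)
        assert km.evaluate(63)[0] == pytest.approx(0.6)
        assert km.evaluate(60.5)[0] == pytest.approx(1.0)

    def test_no_deaths(self):
        km = m.kaplan_meier(records([350] * 4, ["censored"] * 4))
        assert np.all(km.survival == 1.0)

    def test_exit_before_entry_rejected(self):
        with pytest.raises(ValueError):
            m.kaplan_meier(records([59], ["death"]))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            m.kaplan_meier(records([], []))

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(61, 120), min_size=1, max_size=25))
    def test_equals_empirical_survival_without_censoring(self, death_days):
        """With no censoring the product-limit estimate is the empirical
        fraction still alive, at every age (brute-force count oracle)."""
        rec = records(death_days, ["death"] * len(death_days))
        km = m.kaplan_meier(rec)
        days = np.asarray(death_days)
        for t in range(60, 125):
            empirical = np.mean(days > t)
            assert km.evaluate(t)[0] == pytest.approx(empirical, abs=1e-12)


class TestAgeToSize:
    P = m.VBParams(30.0, 0.02, 0.0)

    def test_log_of_curve(self):
        assert m.age_to_size(self.P, 100.0) == pytest.approx(
            np.log(25.93994150290162), abs=1e-9
        )

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            m.age_to_size(m.VBParams(30.0, 0.02, 10.0), 10.0)

    def test_monotone_in_age(self):
        ages = np.linspace(10, 300, 40)
        z = m.age_to_size(self.P, ages)
        assert np.all(np.diff(z) > 0)


class TestSurvivalLogistic:
    def test_size_independent_limit(self):
        """Constant daily survival gives a flat curve at that level."""
        days = np.arange(61, 101)
        surv = 0.9 ** (days - 60)
        km = m.KMCurve(
            entry=60.0,
            times=days.astype(float),
            survival=surv,
            at_risk=np.full(days.size, 100.0),
            events=np.ones(days.size),
        )
        s = m.fit_survival_logistic(km, m.VBParams(30.0, 0.02, 0.0))
        z = np.log(m.vb_length(m.VBParams(30.0, 0.02, 0.0), days.astype(float)))
        assert s.slope == pytest.approx(0.0, abs=1e-9)
        assert np.asarray(s(z)) == pytest.approx(np.full(days.size, 0.9), abs=1e-6)

    def test_glm_recovery_across_seeds(self):
        """Daily survival generated from a known logistic of size is
        recovered within the Wald 95% CI in at least 90% of seeds."""
        params = m.VBParams(25.0, 0.017, -6.0)
        true_int, true_slope = 10.0, -2.0
        cover_int = cover_slope = 0
        n_seeds = 50
        for seed in range(n_seeds):
            rng = np.random.default_rng(2000 + seed)
            n = 400
            alive = np.ones(n, bool)
            exit_day = np.full(n, 350)
            event = np.full(n, "censored", object)
            for day in range(61, 351):
                z = np.log(m.vb_length(params, float(day)))
                p = expit(true_int + true_slope * z)
                dies = alive & (rng.random(n) > p)
                exit_day[dies] = day
                event[dies] = "death"
                alive &= ~dies
            km = m.kaplan_meier(records(exit_day, event))
            s = m.fit_survival_logistic(km, params)
            cover_int += abs(s.intercept - true_int) <= 1.96 * s.intercept_se
            cover_slope += abs(s.slope - true_slope) <= 1.96 * s.slope_se
        assert cover_int >= 0.9 * n_seeds
        assert cover_slope >= 0.9 * n_seeds

    def test_cumulative_mode_differs(self, cohort, fitted_draws):
        key = "warm_continuous"
        surv = cohort.survival.query(
            "treatment_temp == 'warm' and treatment_food == 'continuous'"
        )
        km = m.kaplan_meier(surv)
        params = fitted_draws.mean_params(key)
        per_step = m.fit_survival_logistic(km, params, mode="per_step")
        cumulative = m.fit_survival_logistic(km, params, mode="cumulative")
        # cumulative survival is far below the daily survival probability
        z = 3.0
        assert cumulative(z) < per_step(z)

    def test_empty_km_rejected(self):
        km = m.KMCurve(60.0, np.array([]), np.array([]), np.array([]), np.array([]))
        with pytest.raises(ValueError):
            m.fit_survival_logistic(km, m.VBParams(30.0, 0.02, 0.0))


class TestReproductionProbability:
    def test_midpoint(self):
        fp = m.reproduction_probability(z_mat=2.8, steepness=50.0)
        assert fp(2.8) == pytest.approx(0.5)

    def test_step_limit(self):
        fp = m.reproduction_probability(z_mat=2.8, steepness=500.0)
        assert fp(2.9) == pytest.approx(1.0, abs=1e-9)
        assert fp(2.7) == pytest.approx(0.0, abs=1e-9)

    def test_monotone(self):
        fp = m.reproduction_probability(z_mat=2.8, steepness=50.0)
        z = np.linspace(2.0, 3.5, 100)
        assert np.all(np.diff(np.asarray(fp(z))) >= 0)

    def test_invalid_steepness(self):
        with pytest.raises(ValueError):
            m.reproduction_probability(2.8, steepness=0.0)


class TestFecundity:
    @staticmethod
    def clutch(sizes, counts):
        return pd.DataFrame(
            {
                "tank_id": "t1",
                "treatment_temp": "warm",
                "treatment_food": "continuous",
                "day": 100,
                "female_length_mm": sizes,
                "egg_count": counts,
            }
        )

    def test_constant_counts(self):
        df = self.clutch([15.0, 20.0, 25.0, 30.0] * 25, [7] * 100)
        fec = m.fit_fecundity(df)
        assert fec.b == pytest.approx(0.0, abs=1e-8)
        assert np.exp(fec.a) == pytest.approx(7.0, rel=1e-6)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            m.fit_fecundity(self.clutch([20.0], [5]))

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            m.fit_fecundity(self.clutch([15.0, 20.0, 25.0], [0, 0, 0]))


class TestGrowthResidualSd:
    def test_degenerate_posterior_zero(self):
        th = np.tile([25.0, 0.017, -6.0], (20, 1))
        draws = make_draws({"warm_continuous": th})
        sd = m.growth_residual_sd(draws, "warm_continuous", np.arange(30.0, 200.0))
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_two_draw_hand_computation(self):
        th = np.array([[25.0, 0.017, -6.0], [26.0, 0.018, -6.0]])
        draws = make_draws({"warm_continuous": th})
        ages = np.array([100.0])
        sizes = []
        for L, K, t0 in th:
            p = m.VBParams(L, K, t0)
            sizes.append(np.log(m.vb_step(p, m.vb_length(p, 100.0))))
        expected = np.std(sizes)  # population sd of the two values
        got = m.growth_residual_sd(draws, "warm_continuous", ages)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_duplicating_draws(self, fitted_draws):
        key = fitted_draws.treatments[0]
        ages = np.arange(30.0, 351.0, 20.0)
        sd1 = m.growth_residual_sd(fitted_draws, key, ages)
        doubled = m.PosteriorDraws(
            samples=pd.concat([fitted_draws.samples] * 2, ignore_index=True),
            treatments=fitted_draws.treatments,
            tanks=fitted_draws.tanks,
        )
        sd2 = m.growth_residual_sd(doubled, key, ages)
        assert sd1 == pytest.approx(sd2, abs=1e-12)
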
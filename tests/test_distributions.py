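"""Effect-size mixture: sampling, prevalence math, solvers, typical effect."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import litsim as ls
from litsim.distributions import _MODEL_PARAMS


class TestConstruction:
    def test_presets_match_parameter_table(self):
        expected = {
            "dichotomous": (0.0, 1.0, 0.0),
            "two_peaks": (0.1, 1.0, 0.1),
            "overlapping_peaks": (0.3, 1.0, 0.3),
            "two_normals": (0.1, 0.0, 1.0),
        }
        for name, (sd_a, mu_b, sd_b) in expected.items():
            d = ls.make_distribution(name, w_b=0.5)
            assert (d.sd_a, d.mu_b, d.sd_b) == (sd_a, mu_b, sd_b)
        single = ls.make_distribution("single_normal", sd_a=0.7)
        assert single.w_b == 0.0 and single.sd_a == 0.7

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(sd_a=-0.1, mu_b=1, sd_b=0, w_b=0.5),
            dict(sd_a=0, mu_b=1, sd_b=0, w_b=1.5),
            dict(sd_a=0.2, mu_b=1, sd_b=0, w_b=0.5, model_name="dichotomous"),
            dict(sd_a=1, mu_b=0, sd_b=0, w_b=0.3, model_name="single_normal"),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ls.EffectDistribution(**kwargs)


class TestSampling:
    def test_point_mass_draws_are_exact(self, rng):
        d = ls.make_distribution("dichotomous", w_b=1.0)
        assert ls.sample_effects(d, 3, rng).tolist() == [1.0, 1.0, 1.0]

    def test_mixture_mean_matches_theory(self, rng):
        # mixture mean w_b * mu_b = 0.5; SE of the mean = 0.5/sqrt(n)
        d = ls.make_distribution("dichotomous", w_b=0.5)
        draws = ls.sample_effects(d, 100_000, rng)
        se = 0.5 / np.sqrt(draws.size)
        assert abs(draws.mean() - 0.5) < 3 * se

    def test_single_normal_spread_matches_theory(self, rng):
        d = ls.make_distribution("single_normal", sd_a=1.0)
        draws = ls.sample_effects(d, 100_000, rng)
        # SE of the SD of a normal sample is about sd/sqrt(2n)
        assert abs(draws.std(ddof=1) - 1.0) < 3 / np.sqrt(2 * draws.size)

    @pytest.mark.parametrize("model,param", [("two_peaks", {"w_b": 0.4}),
                                             ("two_normals", {"w_b": 0.27}),
                                             ("single_normal", {"sd_a": 0.74})])
    def test_empirical_prevalence_matches_analytic(self, model, param, rng):
        d = ls.make_distribution(model, **param)
        p = ls.true_prevalence(d)
        draws = ls.sample_effects(d, 100_000, rng)
        phat = (np.abs(draws) > 0.5).mean()
        assert abs(phat - p) < 3 * np.sqrt(p * (1 - p) / draws.size)

    def test_nonpositive_count_rejected(self, rng):
        with pytest.raises(ValueError):
            ls.sample_effects(ls.make_distribution("dichotomous", w_b=0.5), 0, rng)


class TestPrevalence:
    def test_standard_normal_tail_mass(self):
        # 2(1 - Phi(0.5)) = 0.6171: the ceiling quoted for the wide normal
        d = ls.make_distribution("single_normal", sd_a=1.0)
        assert ls.true_prevalence(d, 0.5) == pytest.approx(0.6171, abs=5e-4)

    def test_dichotomous_prevalence_equals_weight(self):
        d = ls.make_distribution("dichotomous", w_b=0.5)
        assert ls.true_prevalence(d, 0.5) == 0.5

    def test_narrow_normal_tail_mass(self):
        # 2(1 - Phi(2.5)) = 0.01242: mass of N(0, 0.2) beyond 0.5
        d = ls.EffectDistribution(sd_a=0.2, mu_b=0, sd_b=0, w_b=0.0)
        assert ls.true_prevalence(d, 0.5) == pytest.approx(0.01242, abs=5e-6)

    def test_monotone_in_sd(self):
        prevs = [
            ls.true_prevalence(ls.make_distribution("single_normal", sd_a=s))
            for s in (0.3, 0.5, 0.8, 1.5, 4.0)
        ]
        assert prevs == sorted(prevs)

    def test_monotone_in_weight(self):
        prevs = [
            ls.true_prevalence(ls.make_distribution("two_peaks", w_b=w))
            for w in (0.1, 0.3, 0.5, 0.7, 0.9)
        ]
        assert prevs == sorted(prevs)


class TestSolvers:
    def test_weight_solver_linear_oracle(self):
        # independent oracle: prevalence is linear in w, so solve by hand
        # from each component's two-tailed mass
        p_a = 2 * stats.norm.sf(0.5 / 0.1)
        p_b = stats.norm.sf(0.5, loc=1, scale=0.1) + stats.norm.cdf(-0.5, loc=1, scale=0.1)
        expected = (0.5 - p_a) / (p_b - p_a)
        got = ls.solve_weight_for_prevalence("two_peaks", 0.5)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(0.5, abs=1e-5)

    def test_unachievable_target_reports_bounds(self):
        with pytest.raises(ls.UnachievablePrevalence) as err:
            ls.solve_weight_for_prevalence("two_normals", 2 / 3)
        lo, hi = err.value.bounds
        assert hi == pytest.approx(0.6171, abs=5e-4)
        assert lo < 1e-5

    def test_boundary_target_gives_zero_weight(self):
        p_a = 2 * stats.norm.sf(0.5 / 0.3)
        assert ls.solve_weight_for_prevalence("overlapping_peaks", p_a) == pytest.approx(0.0, abs=1e-12)

    def test_sd_solver_footnote_value(self):
        # prevalence 0.617 is (to the printed precision) that of N(0, 1)
        assert ls.solve_sd_for_prevalence(0.617) == pytest.approx(1.0, abs=1e-3)

    def test_sd_solver_round_trip(self):
        target = ls.true_prevalence(ls.make_distribution("single_normal", sd_a=0.3))
        assert ls.solve_sd_for_prevalence(target) == pytest.approx(0.3, abs=1e-10)

    def test_sd_solver_high_prevalence(self):
        # the SD used in the sweeps for ~90% prevalence is about 4
        assert ls.solve_sd_for_prevalence(0.9) == pytest.approx(3.979, abs=2e-3)

    @pytest.mark.parametrize("bad", [0.0, 1.0])
    def test_sd_solver_rejects_degenerate_targets(self, bad):
        with pytest.raises(ValueError):
            ls.solve_sd_for_prevalence(bad)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        target=st.floats(0.05, 0.95),
        model=st.sampled_from(["two_peaks", "overlapping_peaks", "two_normals", "single_normal"]),
    )
    def test_solvers_round_trip(self, target, model):
        lo, hi = ls.achievable_prevalence_bounds(model)
        if not lo <= target <= hi:
            with pytest.raises(ls.UnachievablePrevalence):
                ls.solve_weight_for_prevalence(model, target)
            return
        dist = ls.distribution_for_prevalence(model, target)
        assert ls.true_prevalence(dist) == pytest.approx(target, abs=1e-10)


class TestTypicalTrueEffect:
    def test_dichotomous_typical_effect_is_one(self):
        assert ls.typical_true_effect(ls.make_distribution("dichotomous", w_b=0.5)) == 1.0

    def test_single_normal_matches_truncated_mean(self):
        # E[X | X > 0.5] for N(0,1) = phi(0.5)/(1 - Phi(0.5)) = 1.14108,
        # identical on both tails by symmetry
        d = ls.make_distribution("single_normal", sd_a=1.0)
        assert ls.typical_true_effect(d) == pytest.approx(1.14108, abs=1e-5)

    def test_two_peaks_typical_effect_near_one(self):
        d = ls.make_distribution("two_peaks", w_b=0.5)
        assert ls.typical_true_effect(d) == pytest.approx(1.0, abs=0.01)

    @pytest.mark.parametrize("model,param", [("overlapping_peaks", {"w_b": 0.47}),
                                             ("single_normal", {"sd_a": 1.2})])
    def test_monte_carlo_agrees_with_analytic(self, model, param, rng):
        d = ls.make_distribution(model, **param)
        analytic = ls.typical_true_effect(d)
        mc_draws = 100_000
        mc = ls.typical_true_effect(d, method="monte_carlo", rng=rng, n_draws=mc_draws)
        # MC SE of a conditional mean: sd of |ES| over the true subset
        sub = np.abs(ls.sample_effects(d, mc_draws, rng))
        sub = sub[sub > 0.5]
        se = sub.std() / np.sqrt(sub.size)
        assert abs(mc - analytic) < 3 * se

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(target=st.floats(0.05, 0.9))
    def test_typical_effect_exceeds_threshold(self, target):
        d = ls.distribution_for_prevalence("single_normal", target)
        assert ls.typical_true_effect(d) >= 0.5

    def test_zero_prevalence_is_an_error(self):
        with pytest.raises(ValueError):
            ls.typical_true_effect(ls.make_distribution("dichotomous", w_b=0.0))


def test_model_name_listing_is_complete():
    assert set(ls.MODEL_NAMES) == set(_MODEL_PARAMS)
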
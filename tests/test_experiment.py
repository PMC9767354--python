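"""Power math, single experiments, and the publication decision."""

import numpy as np
import pytest
from scipy import stats

import litsim as ls
from litsim.experiment import run_experiment_batch


class TestPower:
    def test_null_effect_power_equals_alpha(self):
        assert ls.power_for_sample_size(0.0, 30, alpha=0.05) == pytest.approx(0.05, abs=1e-12)

    def test_unit_effect_n17_hits_80_percent(self):
        assert ls.power_for_sample_size(1.0, 17) >= 0.80

    def test_power_monotone_in_n_and_effect(self):
        by_n = [ls.power_for_sample_size(0.8, n) for n in (5, 10, 20, 40)]
        assert by_n == sorted(by_n)
        by_d = [ls.power_for_sample_size(d, 20) for d in (0.2, 0.5, 0.8, 1.2)]
        assert by_d == sorted(by_d)

    @pytest.mark.parametrize("effect,n", [(0.5, 20), (0.8, 12), (1.0, 17), (1.2, 40)])
    def test_against_statsmodels_oracle(self, effect, n):
        smp = pytest.importorskip("statsmodels.stats.power")
        oracle = smp.TTestIndPower().power(effect_size=effect, nobs1=n, alpha=0.05)
        assert ls.power_for_sample_size(effect, n) == pytest.approx(oracle, abs=1e-6)

    def test_simulated_rejection_rate_matches_power(self, rng):
        # independent check of the noncentral-t formula by brute force
        effect, n, reps = 1.0, 17, 100_000
        _, pvals = run_experiment_batch(np.full(reps, effect), n, rng)
        rate = (pvals < 0.05).mean()
        power = ls.power_for_sample_size(effect, n)
        assert abs(rate - power) < 3 * np.sqrt(power * (1 - power) / reps)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            ls.power_for_sample_size(1.0, 1)


class TestSampleSize:
    def test_unit_effect_80_power_needs_17(self):
        n = ls.sample_size_for_power(ls.PowerSpec(power=0.8, reference_effect=1.0))
        assert n == 17

    def test_returned_n_is_minimal(self):
        spec = ls.PowerSpec(power=0.8, reference_effect=0.6)
        n = ls.sample_size_for_power(spec)
        assert ls.power_for_sample_size(0.6, n) >= 0.8
        assert ls.power_for_sample_size(0.6, n - 1) < 0.8

    def test_low_power_gives_small_n(self):
        spec = ls.PowerSpec(power=0.2, reference_effect=1.0)
        n = ls.sample_size_for_power(spec)
        assert 2 <= n <= 4
        assert ls.power_for_sample_size(1.0, n) >= 0.2

    def test_larger_reference_effect_never_needs_more_samples(self):
        for d in (0.3, 0.5, 0.9):
            n1 = ls.sample_size_for_power(ls.PowerSpec(power=0.8, reference_effect=d))
            n2 = ls.sample_size_for_power(ls.PowerSpec(power=0.8, reference_effect=2 * d))
            assert n2 <= n1

    def test_reference_resolution_rules(self):
        d = ls.make_distribution("single_normal", sd_a=1.0)
        spec = ls.PowerSpec(power=0.8, reference="min_effect")
        assert ls.experiment.resolve_reference_effect(spec, d).reference_effect == 0.5
        spec = ls.PowerSpec(power=0.8, reference="twice_min_effect")
        assert ls.experiment.resolve_reference_effect(spec, d).reference_effect == 1.0
        spec = ls.PowerSpec(power=0.8, reference="typical_true_mean")
        resolved = ls.experiment.resolve_reference_effect(spec, d)
        assert resolved.reference_effect == pytest.approx(1.14108, abs=1e-5)


class TestRunExperiment:
    def test_null_pvalues_are_uniform(self, rng):
        reps = 20_000
        _, pvals = run_experiment_batch(np.zeros(reps), 10, rng)
        rate = (pvals < 0.05).mean()
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_estimate_centered_on_true_effect(self, rng):
        n = 10_000
        res = ls.run_experiment(1.0, n, rng)
        assert abs(res.estimate - 1.0) < 3 * np.sqrt(2 / n)

    def test_estimate_distribution_symmetric_in_sign(self):
        est_pos, _ = run_experiment_batch(np.full(4000, 0.8), 10, np.random.default_rng(3))
        est_neg, _ = run_experiment_batch(np.full(4000, -0.8), 10, np.random.default_rng(3))
        # same RNG stream: identical noise, mirrored signal
        assert stats.kstest(est_pos, -est_neg).pvalue > 0.01

    def test_scalar_and_batch_paths_agree(self):
        # same seed, batch of one: identical draws, identical result
        single = ls.run_experiment(0.7, 9, np.random.default_rng(11))
        est, p = run_experiment_batch(np.array([0.7]), 9, np.random.default_rng(11))
        assert single.estimate == est[0] and single.p_value == p[0]


class TestPublishDecision:
    def _result(self, p, estimate=0.8, true_es=1.0, n=10):
        return ls.ExperimentResult(true_es=true_es, estimate=estimate, p_value=p, n_per_group=n)

    def test_significant_first_result_published_unchanged(self, rng):
        res = ls.publish_decision(self._result(0.01), bias=0.0, rng=rng)
        assert res.published and res.repeats == 0

    def test_nonsignificant_without_bias_is_shelved(self, rng):
        res = ls.publish_decision(self._result(0.20), bias=0.0, rng=rng)
        assert not res.published

    def test_full_bias_pushes_to_significance(self, rng):
        res = ls.publish_decision(self._result(0.20, true_es=0.0), bias=1.0, rng=rng)
        assert res.published and res.p_value < 0.05 and res.repeats >= 1

    def test_null_repeat_count_is_geometric(self, rng):
        # each re-run succeeds w.p. alpha, so E[repeats] = 1/alpha
        reps = [
            ls.publish_decision(self._result(0.5, true_es=0.0), bias=1.0, rng=rng).repeats
            for _ in range(800)
        ]
        mean = np.mean(reps)
        se = np.std(reps, ddof=1) / np.sqrt(len(reps))
        assert abs(mean - 20.0) < 3 * se

    def test_magnitude_rule_gates_on_estimate(self, rng):
        res = ls.publish_decision(
            self._result(0.20, true_es=1.0),
            bias=1.0,
            rng=rng,
            rule="significance_and_magnitude",
        )
        assert res.published and abs(res.estimate) > 0.5 and res.p_value < 0.05

    def test_repeat_cap_flags_unsatisfiable_rule(self, rng):
        # |estimate| > 50 is out of reach at n = 10, SD 1
        with pytest.raises(ls.RepeatCapExceeded):
            ls.publish_decision(
                self._result(0.20, true_es=0.0),
                bias=1.0,
                rng=rng,
                rule="significance_and_magnitude",
                min_effect=50.0,
                repeat_cap=100,
            )
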
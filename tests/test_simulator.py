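"""Trial simulation, hypothesis tests and aggregated operating characteristics."""

import numpy as np
import pytest
from scipy.special import expit

from caraflgi.simulate import (
    SCENARIO_TWO_ARM_EFFECT,
    SCENARIO_TWO_ARM_NULL,
    SCENARIO_THREE_ARM,
    TrialConfig,
    TrialResult,
    bonferroni_decisions,
    calibrate_test_cutoff,
    comparison_pvalue,
    fisher_exact_pvalue,
    operating_characteristics,
    simulate_trial,
    wald_test_adjusted_difference,
)

from _oracles import fisher_two_sided_oracle


def _cfg(rule, N=60, T=1, scenario=SCENARIO_TWO_ARM_EFFECT, **kw):
    return TrialConfig(n_patients=N, n_treatments=T, rule=rule, **scenario, **kw)


class TestSimulateTrial:
    def test_null_scenario_failure_rate_is_analytic(self, rng):
        # all arms share p = Expit(0.6482) whatever the allocation
        cfg = _cfg({"name": "er"}, N=450, scenario=SCENARIO_TWO_ARM_NULL)
        res = simulate_trial(cfg, rng)
        fail = 1.0 - res.outcomes.mean()
        assert fail == pytest.approx(1 - expit(0.6482), abs=0.08)

    def test_degenerate_all_success_model(self, rng):
        cfg = TrialConfig(
            n_patients=40, n_treatments=1, rule={"name": "er"},
            success_probs=[[1.0, 1.0], [1.0, 1.0]],
        )
        res = simulate_trial(cfg, rng)
        assert res.outcomes.sum() == 40

    def test_zero_covariate_probability_never_allocates_that_level(self, rng):
        cfg = TrialConfig(
            n_patients=40, n_treatments=1, rule={"name": "er"},
            covariate_q=0.0, **SCENARIO_TWO_ARM_EFFECT,
        )
        res = simulate_trial(cfg, rng)
        assert (res.covariates == 0).all()

    @pytest.mark.parametrize(
        "rule",
        [
            {"name": "er"},
            {"name": "spbd", "m": 10},
            {"name": "cara1", "block_size": 10},
            {"name": "thompson", "block_size": 10},
            {"name": "gi"},
            {"name": "flgi", "block_size": 10},
            {"name": "cflgi", "block_size": 10},
        ],
    )
    def test_successes_plus_failures_conserve_n(self, rule, table_small, rng):
        cfg = _cfg(rule, N=60, burn_in=20, thompson_draws=500)
        res = simulate_trial(cfg, rng, table_small)
        succ = int(res.outcomes.sum())
        fail = int((1 - res.outcomes).sum())
        assert succ + fail == 60
        assert res.treatments.min() >= 0 and res.treatments.max() <= 1

    def test_spbd_balances_each_stratum(self, rng):
        cfg = _cfg({"name": "spbd", "m": 10}, N=400)
        res = simulate_trial(cfg, rng)
        for z in (0, 1):
            sel = res.treatments[res.covariates == z]
            n_complete = (sel.size // 10) * 10
            counts = np.bincount(sel[:n_complete], minlength=2)
            assert counts[0] == counts[1]

    def test_missing_table_rejected(self, rng):
        with pytest.raises(ValueError, match="table"):
            simulate_trial(_cfg({"name": "gi"}), rng)

    def test_master_seed_reproducibility(self, table_small):
        cfg = _cfg({"name": "flgi", "block_size": 10}, N=60)
        a = operating_characteristics(cfg, 5, np.random.default_rng(42), table_small)
        b = operating_characteristics(cfg, 5, np.random.default_rng(42), table_small)
        assert a.enf_mean == b.enf_mean
        np.testing.assert_array_equal(a.alloc_prop_mean, b.alloc_prop_mean)
        assert a.power == b.power


class TestConfigValidation:
    def test_block_size_must_divide_n(self):
        with pytest.raises(ValueError):
            _cfg({"name": "flgi", "block_size": 7}, N=60)

    def test_negative_covariate_probability_rejected(self):
        with pytest.raises(ValueError):
            TrialConfig(
                n_patients=10, n_treatments=1, rule={"name": "er"},
                covariate_q=[-0.1, 1.1], **SCENARIO_TWO_ARM_NULL,
            )

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            _cfg({"name": "nope"})

    def test_spbd_block_divisibility(self):
        with pytest.raises(ValueError):
            _cfg({"name": "spbd", "m": 5})

    def test_best_arms_resolution(self):
        cfg = TrialConfig(
            n_patients=30, n_treatments=2, rule={"name": "er"}, **SCENARIO_THREE_ARM
        )
        np.testing.assert_array_equal(cfg.resolved_best_arms(), [2, 1])
        null = _cfg({"name": "er"}, scenario=SCENARIO_TWO_ARM_NULL)
        np.testing.assert_array_equal(null.resolved_best_arms(), [0, 0])


class TestHypothesisTests:
    def _balanced_result(self):
        # two identical arms, identical outcomes: no evidence of difference
        covs = np.zeros(200, dtype=int)
        trts = np.tile([0, 1], 100)
        outs = np.tile([1, 1, 0, 0], 50)
        return TrialResult(covs, trts, outs.astype(np.int8), 2, 1)

    def test_identical_arms_give_p_one(self):
        assert wald_test_adjusted_difference(self._balanced_result()) == pytest.approx(1.0)

    def test_fisher_symmetric_table(self):
        assert fisher_exact_pvalue([[5, 5], [5, 5]]) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "table", [[[10, 0], [0, 10]], [[7, 3], [2, 8]], [[1, 9], [5, 5]]]
    )
    def test_fisher_matches_enumeration_oracle(self, table):
        assert fisher_exact_pvalue(table) == pytest.approx(
            fisher_two_sided_oracle(table), rel=1e-9
        )

    def test_fisher_row_swap_invariance(self):
        assert fisher_exact_pvalue([[7, 3], [2, 8]]) == pytest.approx(
            fisher_exact_pvalue([[2, 8], [7, 3]]), rel=1e-12
        )

    def test_fisher_empty_margin(self):
        assert fisher_exact_pvalue([[0, 0], [3, 4]]) == 1.0

    def test_bonferroni(self):
        np.testing.assert_array_equal(
            bonferroni_decisions([0.02, 0.04], 0.05, 2), [True, False]
        )
        np.testing.assert_array_equal(bonferroni_decisions([0.04], 0.05, 1), [True])
        assert not bonferroni_decisions([1.0, 1.0], 0.05, 2).any()


class TestCalibration:
    def test_nominal_alpha_one_exceeds_all_pvalues(self, rng):
        cfg = _cfg({"name": "er"}, N=40, scenario=SCENARIO_TWO_ARM_NULL,
                   test={"name": "fisher"})
        cut = calibrate_test_cutoff(cfg, 50, 1.0, rng)
        assert cut >= 0.99

    def test_er_wald_cutoff_near_nominal(self, rng):
        cfg = _cfg({"name": "er"}, N=120, scenario=SCENARIO_TWO_ARM_NULL)
        cut = calibrate_test_cutoff(cfg, 400, 0.05, rng)
        assert 0.01 < cut < 0.12  # asymptotically calibrated test

    def test_fresh_sample_self_consistency(self, rng):
        # rejection rate at the calibrated cutoff on an independent null
        # sample stays within binomial error of the nominal level
        cfg = _cfg({"name": "er"}, N=80, scenario=SCENARIO_TWO_ARM_NULL,
                   test={"name": "fisher"})
        reps = 400
        cut = calibrate_test_cutoff(cfg, reps, 0.05, rng)
        fresh = np.random.default_rng(99).spawn(reps)
        ps = np.array(
            [comparison_pvalue(simulate_trial(cfg, s), 1, cfg) for s in fresh]
        )
        rate = (ps <= cut).mean()
        assert abs(rate - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / reps) + 0.02


class TestOperatingCharacteristics:
    def test_null_allocations_tend_to_balance(self, table_small):
        # any rule allocates ~1/(T+1) per arm on average under the null
        for rule in ({"name": "cara1", "block_size": 10}, {"name": "flgi", "block_size": 10}):
            cfg = _cfg(rule, N=60, scenario=SCENARIO_TWO_ARM_NULL, burn_in=20,
                       test={"name": "fisher", "cutoff": 0.02})
            oc = operating_characteristics(cfg, 300, np.random.default_rng(8), table_small)
            se = oc.alloc_prop_sd[0] / np.sqrt(oc.replications)
            assert abs(oc.alloc_prop_mean[0] - 0.5) <= 3 * se + 0.01

    def test_single_replication_flags_sd(self, rng):
        cfg = _cfg({"name": "er"})
        oc = operating_characteristics(cfg, 1, rng)
        assert np.isnan(oc.enf_sd)
        assert np.isnan(oc.alloc_prop_sd).all()
        assert oc.enf_mean + oc.ens_mean == 60

    def test_pstar_is_covariate_weighted_best_proportion(self, rng):
        cfg = _cfg({"name": "er"}, N=300)
        oc = operating_characteristics(cfg, 100, rng)
        # ER gives every arm half of each level; the best arm is arm 1 here
        assert oc.pstar_mean == pytest.approx(0.5, abs=0.02)
        assert oc.best_prop_mean[0] == pytest.approx(0.5, abs=0.03)

    def test_three_arm_controlled_rule_protects_control(self, table_full):
        cfg = TrialConfig(
            n_patients=300, n_treatments=2, rule={"name": "cflgi", "block_size": 50},
            test={"name": "fisher", "cutoff": 0.02}, **SCENARIO_THREE_ARM,
        )
        oc = operating_characteristics(cfg, 30, np.random.default_rng(5), table_full)
        assert oc.alloc_prop_mean[0] == pytest.approx(1 / 3, abs=0.02)
        assert not np.isnan(oc.power_by_level).any()
        assert oc.ens_mean > 120  # beats balanced ENS in this scenario

    def test_better_best_arm_never_hurts_gi_successes(self, table_small):
        # coarse monotonicity of patient benefit in the effect size
        means = []
        for p1 in (0.5, 0.7, 0.9):
            cfg = TrialConfig(
                n_patients=60, n_treatments=1, rule={"name": "gi"},
                success_probs=[[0.5, p1], [0.5, p1]],
                test={"name": "fisher", "cutoff": 0.02},
            )
            oc = operating_characteristics(cfg, 200, np.random.default_rng(17), table_small)
            means.append((oc.ens_mean, oc.ens_sd / np.sqrt(200)))
        for (lo, se_lo), (hi, se_hi) in zip(means, means[1:]):
            assert hi >= lo - 3 * np.hypot(se_lo, se_hi)
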
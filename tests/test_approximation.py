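"""Aggregate-data approximation of the unit information and interaction variance."""

import math
from dataclasses import replace

import numpy as np
import pytest

from ipdma_power import (
    CovariateSpec,
    Scenario,
    TrialAggregate,
    joint_cell_probabilities,
    trial_variance,
    unit_information_analytic,
    unit_information_monte_carlo,
    weight_option_i,
    weight_option_ii,
    weight_option_iii,
    with_subgroup_offsets,
)
from ipdma_power.errors import ConfigurationError, UnsupportedCovariateError

LAM = math.log(1.3)


def closed_form_binary_option_i(trial):
    """Independent oracle: for the saturated binary design with w=1,
    [I*^-1]_(4,4) = sum over the four cells of 1/p, so var = that / e."""
    cells = joint_cell_probabilities(trial)
    return sum(1.0 / p for p in cells.values()) / trial.e


class TestWeightOptions:
    def test_option_i_trial_eight(self, sex_trials):
        w, n_eff = weight_option_i(sex_trials[7])
        assert w == 1.0 and n_eff == 11

    def test_option_i_no_censoring_boundary(self):
        trial = TrialAggregate("B", 50, 50, 50, 50, covariate=CovariateSpec.binary(0.5, 0.5))
        w, n_eff = weight_option_i(trial)
        assert (w, n_eff) == (1.0, trial.n)

    def test_option_ii_reduces_to_event_proportions(self, sex_trials):
        # gamma = lam = 0: w(x, z) collapses to the arm's event proportion e/n
        trial = sex_trials[0]
        sc = Scenario(lambda_target=0.0, gamma=0.0, wij_option="ii")
        assert weight_option_ii(trial, sc, 0, 1.0) == pytest.approx(13 / 750, rel=1e-12)
        assert weight_option_ii(trial, sc, 1, 0.0) == pytest.approx(9 / 780, rel=1e-12)

    def test_option_ii_interaction_ratio(self, age_trials):
        # ten more years of age multiplies the treated-arm weight by the interaction HR
        trial = age_trials[1]
        sc = Scenario(lambda_target=LAM, wij_option="ii")
        zbar = trial.pooled_covariate_mean()
        ratio = weight_option_ii(trial, sc, 1, zbar + 10) / weight_option_ii(trial, sc, 1, zbar)
        assert ratio == pytest.approx(1.3, rel=1e-12)

    def test_option_ii_requires_followup(self):
        trial = TrialAggregate("T", 100, 100, 20, 15, covariate=CovariateSpec.binary(0.4, 0.4))
        with pytest.raises(ConfigurationError, match="option \\(i\\)"):
            weight_option_ii(trial, Scenario(lambda_target=LAM, wij_option="ii"), 0, 0)

    def test_option_ii_zero_event_arm_rejected(self):
        trial = TrialAggregate("T", 100, 100, 20, 0, covariate=CovariateSpec.binary(0.4, 0.4),
                               f_control=2.0, f_treatment=2.0)
        with pytest.raises(ConfigurationError, match="zero events"):
            weight_option_ii(trial, Scenario(lambda_target=LAM, wij_option="ii"), 1, 0)

    def test_option_iii_with_arm_means_equals_option_ii(self, sex_trials):
        trial = sex_trials[1]
        sub = {(arm, lvl): getattr(trial, f"f_{arm}")
               for arm in ("control", "treatment") for lvl in (0, 1)}
        trial3 = replace(trial, subgroup_followup=sub)
        sc2 = Scenario(lambda_target=LAM, wij_option="ii")
        sc3 = Scenario(lambda_target=LAM, wij_option="iii")
        for x in (0, 1):
            for z in (0, 1):
                assert weight_option_iii(trial3, sc3, x, z) == pytest.approx(
                    weight_option_ii(trial3, sc2, x, z), rel=1e-12)
        assert trial_variance(trial3, sc3).var_lambda == pytest.approx(
            trial_variance(trial, sc2).var_lambda, rel=1e-12)

    def test_option_iii_continuous_unsupported(self, age_trials):
        sc = Scenario(lambda_target=LAM, wij_option="iii")
        with pytest.raises(UnsupportedCovariateError):
            trial_variance(age_trials[0], sc)

    def test_option_iii_missing_subgroup_entry(self, sex_trials):
        sc = Scenario(lambda_target=LAM, wij_option="iii")
        with pytest.raises(ConfigurationError, match="subgroup"):
            trial_variance(sex_trials[0], sc)


class TestAnalyticUnitInformation:
    def test_binary_closed_form_on_random_profiles(self):
        # criterion oracle: symbolic cell closed form vs numeric 4x4 inversion
        rng = np.random.default_rng(2024)
        sc = Scenario(lambda_target=LAM)
        for _ in range(1000):
            n_c, n_t = rng.integers(10, 5000, size=2)
            e_c = rng.integers(1, n_c + 1)
            e_t = rng.integers(1, n_t + 1)
            p_c, p_t = rng.uniform(0.05, 0.95, size=2)
            trial = TrialAggregate("R", int(n_c), int(n_t), int(e_c), int(e_t),
                                   covariate=CovariateSpec.binary(p_c, p_t))
            assert trial_variance(trial, sc).var_lambda == pytest.approx(
                closed_form_binary_option_i(trial), rel=1e-10)

    def test_table2_sex_variances(self, sex_trials, sex_scenario):
        assert trial_variance(sex_trials[7], sex_scenario).var_lambda == pytest.approx(1.910, abs=2e-3)
        assert trial_variance(sex_trials[6], sex_scenario).var_lambda == pytest.approx(0.036, abs=5e-4)

    def test_table2_age_variances(self, age_trials, age_scenario):
        v2 = trial_variance(age_trials[1], age_scenario)
        assert v2.var_lambda == pytest.approx(0.0027, abs=5e-5)  # per year^2
        assert v2.var_lambda_scaled == pytest.approx(v2.var_lambda * 100, rel=1e-12)
        assert trial_variance(age_trials[6], age_scenario).var_lambda == pytest.approx(0.00020, abs=5e-6)

    def test_continuous_identical_arms_closed_form(self):
        # block-inversion oracle: var = 1/(e * p(1-p) * sigma^2) when both arms share z's distribution
        cov = CovariateSpec.continuous_overall(50.0, 8.0)
        trial = TrialAggregate("C", 300, 200, 40, 25, covariate=cov)
        p = trial.prop_treatment
        expected = 1.0 / (trial.e * p * (1 - p) * 8.0**2)
        assert trial_variance(trial, Scenario(lambda_target=LAM)).var_lambda == \
            pytest.approx(expected, rel=1e-10)

    def test_zero_cell_aborts_with_explanation(self):
        trial = TrialAggregate("Z", 100, 100, 20, 20,
                               covariate=CovariateSpec.binary(0.0, 0.5))
        with pytest.raises(ConfigurationError, match="cell"):
            trial_variance(trial, Scenario(lambda_target=LAM))

    def test_matrix_invariants_on_fixture(self, sex_trials, age_trials):
        for trials, opts in ((sex_trials, ("i", "ii")), (age_trials, ("i", "ii"))):
            for t in trials:
                for opt in opts:
                    info = unit_information_analytic(t, Scenario(lambda_target=LAM, wij_option=opt))
                    m = info.matrix
                    assert np.allclose(m, m.T, atol=1e-12)
                    assert np.linalg.eigvalsh(m).min() >= -1e-10
                    assert info.effective_n == (t.e if opt == "i" else t.n)


class TestMonteCarlo:
    def test_agrees_with_analytic_binary(self, sex_trials):
        sc = Scenario(lambda_target=LAM, mc_size=400_000, seed=7)
        mc = unit_information_monte_carlo(sex_trials[7], sc)
        exact = unit_information_analytic(sex_trials[7], sc).variance_of_interaction()
        assert abs(mc.variance_of_interaction() - exact) < 3 * mc.mc_se_44

    def test_agrees_with_analytic_continuous_option_ii(self, age_trials):
        sc = Scenario(lambda_target=LAM, gamma=math.log(1.025), wij_option="ii",
                      mc_size=400_000, seed=11)
        mc = unit_information_monte_carlo(age_trials[6], sc)
        exact = unit_information_analytic(age_trials[6], sc).variance_of_interaction()
        assert abs(mc.variance_of_interaction() - exact) < 3 * mc.mc_se_44

    def test_mc_se_shrinks_with_sample_size(self, sex_trials):
        small = unit_information_monte_carlo(sex_trials[0], Scenario(lambda_target=LAM, mc_size=50_000, seed=3))
        big = unit_information_monte_carlo(sex_trials[0], Scenario(lambda_target=LAM, mc_size=200_000, seed=3))
        ratio = small.mc_se_44 / big.mc_se_44
        assert 1.6 < ratio < 2.5  # ~2 expected from quadrupling the sample

    def test_seed_determinism(self, sex_trials):
        sc = Scenario(lambda_target=LAM, mc_size=50_000, seed=42, expectation_mode="monte_carlo")
        v1 = trial_variance(sex_trials[2], sc)
        v2 = trial_variance(sex_trials[2], sc)
        assert v1.var_lambda == v2.var_lambda
        assert v1.seed == 42


class TestStructuralProperties:
    def test_followup_rescaling_leaves_variance_unchanged(self, sex_trials):
        # time-unit changes cancel: rates scale down as follow-up scales up
        trial = sex_trials[1]
        scaled = replace(trial, f_control=trial.f_control * 12, f_treatment=trial.f_treatment * 12)
        for opt in ("i", "ii"):
            sc = Scenario(lambda_target=LAM, wij_option=opt)
            assert trial_variance(scaled, sc).var_lambda == pytest.approx(
                trial_variance(trial, sc).var_lambda, rel=1e-12)

    def test_variance_decreases_with_covariate_sd(self):
        sc = Scenario(lambda_target=LAM)
        last = math.inf
        for sd in (2.0, 4.0, 8.0, 16.0):
            trial = TrialAggregate("S", 200, 200, 30, 30,
                                   covariate=CovariateSpec.continuous_overall(60.0, sd))
            v = trial_variance(trial, sc).var_lambda
            assert v < last
            last = v

    def test_option_i_variance_halves_when_events_double(self):
        cov = CovariateSpec.binary(0.4, 0.4)
        t1 = TrialAggregate("A", 400, 400, 30, 30, covariate=cov)
        t2 = TrialAggregate("B", 800, 800, 60, 60, covariate=cov)
        sc = Scenario(lambda_target=LAM)
        assert trial_variance(t2, sc).var_lambda == pytest.approx(
            trial_variance(t1, sc).var_lambda / 2, rel=1e-12)

    def test_subgroup_offsets_helper(self, sex_trials):
        trial = with_subgroup_offsets(sex_trials[0], {1: -0.25, 0: +0.25})
        assert trial.subgroup_exp_y("control", 1) == pytest.approx(2.92 - 0.25)
        assert trial.subgroup_exp_y("treatment", 0) == pytest.approx(3.14 + 0.25)
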
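"""Synthetic IPD generation, censoring calibration, and SE agreement with the ML oracle."""

import math

import numpy as np
import pandas as pd
import pytest

from ipdma_power import (
    CovariateSpec,
    ModelParams,
    Scenario,
    SimulationDesign,
    TrialAggregate,
    aggregate_truth,
    calibrate_censoring,
    fit_mle,
    se_agreement_study,
    simulate_trial,
)
from ipdma_power.errors import CalibrationError

LAM = math.log(1.3)


class TestCalibration:
    def test_exponential_mechanism_closed_form(self):
        # constant hazard eta, censor rate c: event fraction = eta/(eta+c)
        cov = CovariateSpec.binary(0.5, 0.5)
        truth = ModelParams(alpha=math.log(0.2), beta=0.0, gamma=0.0, lam=0.0)
        target_c, target_t = 0.3, 0.25
        e_c, e_t = round(400 * target_c), round(400 * target_t)
        trial = TrialAggregate("E", 400, 400, e_c, e_t, covariate=cov,
                               f_control=1.0, f_treatment=1.0)
        cal = calibrate_censoring(trial, truth, "exponential")
        eta = 0.2
        for arm, e_arm in (("control", e_c), ("treatment", e_t)):
            frac = e_arm / 400
            expected = eta * (1 - frac) / frac
            assert cal.params[arm] == pytest.approx(expected, rel=1e-10)
            assert cal.achieved_event_fraction[arm] == pytest.approx(frac, abs=1e-10)

    def test_no_censoring_limit(self):
        cov = CovariateSpec.binary(0.5, 0.5)
        truth = ModelParams(alpha=math.log(0.2))
        trial = TrialAggregate("N", 100, 100, 100, 100, covariate=cov)
        for mech, limit in (("uniform_followup", math.inf), ("fixed_time", math.inf),
                            ("exponential", 0.0)):
            cal = calibrate_censoring(trial, truth, mech)
            assert cal.params["control"] == limit
            assert cal.achieved_event_fraction["control"] == 1.0

    def test_trial_eight_profile_achieved_to_1e6(self, sex_trials):
        trial = sex_trials[7]
        truth = aggregate_truth(trial, Scenario(lambda_target=LAM))
        cal = calibrate_censoring(trial, truth, "uniform_followup")
        assert cal.achieved_event_fraction["control"] == pytest.approx(7 / 131, abs=1e-6)
        assert cal.achieved_event_fraction["treatment"] == pytest.approx(4 / 137, abs=1e-6)

    def test_zero_event_arm_rejected(self):
        trial = TrialAggregate("Z", 100, 100, 5, 0,
                               covariate=CovariateSpec.binary(0.5, 0.5),
                               f_control=1.0, f_treatment=1.0)
        with pytest.raises(CalibrationError, match="zero events"):
            calibrate_censoring(trial, ModelParams(alpha=-2.0), "uniform_followup")


class TestSimulation:
    def test_no_censoring_gives_all_events_and_exponential_means(self):
        truth = ModelParams(alpha=math.log(0.5), beta=math.log(0.8))
        cov = CovariateSpec.binary(0.5, 0.5)
        trial = TrialAggregate("N", 2000, 2000, 2000, 2000, covariate=cov)
        design = SimulationDesign(trial=trial, truth=truth, censoring="exponential", seed=1)
        data = simulate_trial(design, 0)
        assert (data.event == 1).all()
        for x, rate in ((0.0, 0.5), (1.0, 0.4)):
            arm = data[data.x == x]
            se = arm.time.std(ddof=1) / math.sqrt(len(arm))
            assert abs(arm.time.mean() - 1 / rate) < 3 * se

    def test_calibrated_event_fractions_match_fixture_trial_one(self, sex_trials):
        trial = sex_trials[0]
        truth = aggregate_truth(trial, Scenario(lambda_target=LAM))
        design = SimulationDesign(trial=trial, truth=truth, seed=4)
        counts = {"control": [], "treatment": []}
        for rep in range(20):
            d = simulate_trial(design, rep)
            counts["control"].append(d[(d.x == 0)].event.sum())
            counts["treatment"].append(d[(d.x == 1)].event.sum())
        for arm, n_arm, e_arm in (("control", 750, 13), ("treatment", 780, 9)):
            p = e_arm / n_arm
            se = math.sqrt(20 * trial.n * 0.5 * p * (1 - p))  # ~binomial over pooled reps
            assert abs(sum(counts[arm]) - 20 * e_arm) < 3 * se

    def test_seed_determinism(self, synthetic_binary_trial):
        trial, truth = synthetic_binary_trial
        design = SimulationDesign(trial=trial, truth=truth, seed=9)
        a = simulate_trial(design, 3)
        b = simulate_trial(design, 3)
        pd.testing.assert_frame_equal(a, b)
        c = simulate_trial(design, 4)
        assert not a.time.equals(c.time)

    def test_null_interaction_recovery(self):
        truth = ModelParams(alpha=math.log(0.3), beta=-0.1, gamma=0.05, lam=0.0)
        cov = CovariateSpec.binary(0.5, 0.5)
        trial = TrialAggregate("NUL", 20000, 20000, 20000, 20000, covariate=cov)
        design = SimulationDesign(trial=trial, truth=truth, censoring="exponential", seed=17)
        fit = fit_mle(simulate_trial(design, 0))
        assert abs(fit.params.lam) < 3 * math.sqrt(fit.cov[3, 3])


class TestSEAgreement:
    def test_no_censoring_option_i_matches_oracle(self):
        # with every participant an event, w=1 is exact (effective n = e = n)
        truth = ModelParams(alpha=math.log(0.4), beta=math.log(0.9), gamma=0.0, lam=LAM)
        cov = CovariateSpec.binary(0.5, 0.5)
        trial = TrialAggregate("FULL", 1000, 1000, 1000, 1000, covariate=cov,
                               f_control=2.4, f_treatment=2.6)
        design = SimulationDesign(trial=trial, truth=truth, censoring="exponential",
                                  n_replicates=60, seed=31)
        tab = se_agreement_study(design, Scenario(lambda_target=LAM), options=("i",))
        assert tab.loc[0, "ratio_i"] == pytest.approx(1.0, abs=0.05)

    def test_option_ii_tracks_oracle_under_censoring(self, synthetic_binary_trial):
        trial, truth = synthetic_binary_trial
        design = SimulationDesign(trial=trial, truth=truth, n_replicates=80, seed=13)
        tab = se_agreement_study(design, Scenario(lambda_target=LAM), options=("i", "ii"))
        assert abs(tab.loc[0, "ratio_ii"] - 1.0) < 0.25
        assert abs(tab.loc[0, "ratio_i"] - 1.0) < 0.25

    def test_size_sweep_scales_ses(self, synthetic_binary_trial):
        trial, truth = synthetic_binary_trial
        design = SimulationDesign(trial=trial, truth=truth, n_replicates=60,
                                  subset_sizes=(500, 2000), seed=23)
        tab = se_agreement_study(design, Scenario(lambda_target=LAM), options=("i",))
        # SE shrinks roughly as sqrt(size)
        ratio = tab.loc[0, "mean_model_se"] / tab.loc[1, "mean_model_se"]
        assert ratio == pytest.approx(2.0, rel=0.15)
        assert (tab["n_failures"] <= 0.05 * 60).all()


class TestCoxCrossCheck:
    def test_exponential_se_close_to_cox_se(self, synthetic_binary_trial):
        """Independent oracle: on moderately censored exponential data the
        semi-parametric Cox model's interaction SE should nearly match the
        exponential model's (the motivation for using the exponential
        information matrix as the working approximation)."""
        from lifelines import CoxPHFitter

        trial, truth = synthetic_binary_trial
        design = SimulationDesign(trial=trial, truth=truth, seed=77)
        data = simulate_trial(design, 0)
        fit = fit_mle(data)
        exp_se = math.sqrt(fit.cov[3, 3])

        df = data.assign(xz=data.x * data.z)
        cox = CoxPHFitter()
        cox.fit(df, duration_col="time", event_col="event")
        cox_se = cox.standard_errors_["xz"]
        assert exp_se == pytest.approx(cox_se, rel=0.10)
        assert fit.params.lam == pytest.approx(cox.params_["xz"], abs=3 * cox_se)
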
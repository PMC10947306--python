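import math

import numpy as np
import pytest

from ipdma_power import (
    CovariateSpec,
    ModelParams,
    Scenario,
    TrialAggregate,
    linear_predictor,
    load_antihypertensive_example,
)
from ipdma_power.synthetic import _centred_z_nodes, _event_fraction, _expected_followup

LAMBDA_13 = math.log(1.3)


@pytest.fixture(scope="session")
def sex_trials():
    return load_antihypertensive_example("sex")


@pytest.fixture(scope="session")
def age_trials():
    return load_antihypertensive_example("age")


@pytest.fixture()
def sex_scenario():
    return Scenario(lambda_target=LAMBDA_13)


@pytest.fixture()
def age_scenario():
    return Scenario(lambda_target=LAMBDA_13)


def make_consistent_trial(truth: ModelParams, n_control: int, n_treatment: int,
                          covariate: CovariateSpec, mechanism: str = "uniform_followup",
                          param: float = 5.0, trial_id: str = "SYN") -> TrialAggregate:
    """Build a TrialAggregate whose e/n and f are exactly what *truth* plus the
    given censoring mechanism/parameter imply, so simulation and aggregate
    approximation describe the same data-generating process."""
    tmp = TrialAggregate(trial_id, n_control, n_treatment,
                         max(1, n_control // 2), max(1, n_treatment // 2),
                         covariate=covariate, f_control=1.0, f_treatment=1.0)
    counts, followups = {}, {}
    for arm, x, n_arm in (("control", 0.0, n_control), ("treatment", 1.0, n_treatment)):
        z, w = _centred_z_nodes(tmp, arm)
        eta = np.exp(linear_predictor(truth, x, z))
        ef = float(np.sum(w * _event_fraction(mechanism, eta, param)))
        fu = float(np.sum(w * _expected_followup(mechanism, eta, param)))
        counts[arm] = int(round(n_arm * ef))
        followups[arm] = fu
    return TrialAggregate(trial_id, n_control, n_treatment,
                          counts["control"], counts["treatment"],
                          covariate=covariate,
                          f_control=followups["control"], f_treatment=followups["treatment"])


@pytest.fixture(scope="session")
def synthetic_binary_trial():
    """Mid-size two-arm trial (n=2000, balanced, binary covariate 50/50,
    event fraction ~0.3 under uniform administrative censoring)."""
    truth = ModelParams(alpha=math.log(0.15), beta=math.log(0.8), gamma=0.0, lam=math.log(1.3))
    cov = CovariateSpec.binary(0.5, 0.5)
    trial = make_consistent_trial(truth, 1000, 1000, cov, "uniform_followup", 5.0)
    return trial, truth
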
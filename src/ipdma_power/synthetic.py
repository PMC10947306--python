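"""Synthetic participant-level data matching a trial's aggregate profile.

Generates exponential event times from the interaction model, with a
censoring mechanism calibrated so the expected event fraction per arm matches
the aggregate e/n (and mean observed follow-up approximates f). This lets the
aggregate-data approximation engine be validated against the participant-level
maximum-likelihood oracle without any external dataset: simulate many
replicates, fit each by ML, and compare the approximate SEs of the interaction
with the mean model-based SE and the empirical SD of the estimates.

Continuous covariates are simulated on the centred scale (z minus the trial's
pooled mean), so the truth parameters carry the same interpretation as the
approximation engine's alpha_hat (control log rate at the mean covariate) and
beta_hat (rate ratio at the mean covariate).

Censoring mechanisms
--------------------
uniform_followup : administrative censoring C ~ Uniform(0, b) per arm;
    b is calibrated (the default, giving mean follow-up roughly f).
fixed_time : all participants censored at a common horizon tau per arm.
exponential : random censoring C ~ Exponential(rate c) per arm; the expected
    event fraction has the closed form eta/(eta + c), handy for testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import brentq

from .aggregate import Scenario, TrialAggregate
from .approximation import trial_variance
from .errors import CalibrationError, IPDMAPowerError, ValidationError
from .exponential import FitResult, ModelParams, fit_mle, linear_predictor

__all__ = [
    "SimulationDesign",
    "CensoringCalibration",
    "calibrate_censoring",
    "simulate_trial",
    "se_agreement_study",
    "aggregate_truth",
]

Mechanism = Literal["uniform_followup", "fixed_time", "exponential"]
_GH_NODES = 40


@dataclass(frozen=True)
class SimulationDesign:
    """A replicated simulation matched to one trial's aggregate profile.

    ``truth`` is on the centred covariate scale (per single covariate unit);
    ``subset_sizes`` optionally sweeps smaller sample sizes (each a fresh
    synthetic draw of that size, not a resample of one dataset).
    """

    trial: TrialAggregate
    truth: ModelParams
    censoring: Mechanism = "uniform_followup"
    n_replicates: int = 200
    subset_sizes: tuple[int, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValidationError(f"n_replicates must be >= 1, got {self.n_replicates}")
        if self.subset_sizes is not None:
            object.__setattr__(self, "subset_sizes", tuple(int(s) for s in self.subset_sizes))
            for s in self.subset_sizes:
                if not (4 <= s <= self.trial.n):
                    raise ValidationError(f"subset size {s} outside [4, n={self.trial.n}]")
        if self.censoring not in ("uniform_followup", "fixed_time", "exponential"):
            raise ValidationError(f"unknown censoring mechanism {self.censoring!r}")


@dataclass(frozen=True)
class CensoringCalibration:
    """Calibrated per-arm censoring parameters and the moments they achieve.

    ``params`` maps arm -> mechanism parameter (b, tau or rate c); ``inf``
    (or rate 0) means the no-censoring limit. ``achieved_event_fraction`` and
    ``expected_followup`` report the implied E[event] and E[min(T, C)].
    """

    mechanism: Mechanism
    params: dict[str, float]
    achieved_event_fraction: dict[str, float]
    expected_followup: dict[str, float]


def aggregate_truth(trial: TrialAggregate, scenario: Scenario) -> ModelParams:
    """Generating parameters implied by the aggregate data: control log rate and
    log rate ratio from e/(n f), plus the scenario's gamma and per-unit lambda."""
    from .approximation import _aggregate_rates

    alpha, beta = _aggregate_rates(trial)
    return ModelParams(alpha=alpha, beta=beta, gamma=scenario.gamma,
                       lam=scenario.per_unit_lambda(trial.covariate))


def _centred_z_nodes(trial: TrialAggregate, arm: str) -> tuple[np.ndarray, np.ndarray]:
    """Quadrature nodes/weights of the arm's centred covariate distribution."""
    cov = trial.covariate
    zbar = trial.pooled_covariate_mean()
    if cov.kind == "binary":
        p = cov.arm_mean(arm)
        return np.array([0.0 - zbar, 1.0 - zbar]), np.array([1 - p, p])
    nodes, weights = hermegauss(_GH_NODES)  # E[f(N(0,1))] = sum w f(node) / sqrt(2 pi)
    weights = weights / weights.sum()
    m = cov.arm_mean(arm) - zbar
    s = cov.sd_control if arm == "control" else cov.sd_treatment
    return m + s * nodes, weights


def _event_fraction(mechanism: Mechanism, eta: np.ndarray, param: float) -> np.ndarray:
    """P(T < C) for T ~ Exp(eta) under each censoring mechanism."""
    eta = np.asarray(eta, dtype=float)
    if not np.isfinite(param):  # no-censoring limit for uniform/fixed horizons
        return np.ones_like(eta)
    if mechanism == "uniform_followup":
        if param <= 0:
            return np.zeros_like(eta)
        x = eta * param
        return 1.0 - (1.0 - np.exp(-x)) / x
    if mechanism == "fixed_time":
        return 1.0 - np.exp(-eta * param)
    return eta / (eta + param)  # exponential; param = 0 gives 1 (no censoring)


def _expected_followup(mechanism: Mechanism, eta: np.ndarray, param: float) -> np.ndarray:
    """E[min(T, C)] for T ~ Exp(eta) under each mechanism."""
    eta = np.asarray(eta, dtype=float)
    if not np.isfinite(param):
        return 1.0 / eta
    if mechanism == "uniform_followup":
        x = eta * param
        return 1.0 / eta - (1.0 - np.exp(-x)) / (param * eta ** 2)
    if mechanism == "fixed_time":
        return (1.0 - np.exp(-eta * param)) / eta
    return 1.0 / (eta + param)


def calibrate_censoring(trial: TrialAggregate, truth: ModelParams,
                        mechanism: Mechanism = "uniform_followup") -> CensoringCalibration:
    """Solve per arm for the censoring parameter matching the aggregate event fraction.

    For each arm, finds the mechanism parameter such that the expected event
    fraction (averaged over the arm's covariate distribution) equals e/n,
    by one-dimensional root finding. An event fraction of 1 returns the
    no-censoring limit. Reports the achieved moments, including the implied
    mean observed follow-up.
    """
    params: dict[str, float] = {}
    achieved: dict[str, float] = {}
    followup: dict[str, float] = {}
    for arm, x in (("control", 0.0), ("treatment", 1.0)):
        n_arm = trial.n_control if arm == "control" else trial.n_treatment
        e_arm = trial.e_control if arm == "control" else trial.e_treatment
        target = e_arm / n_arm
        if target == 0:
            raise CalibrationError(
                f"trial {trial.trial_id}: {arm} arm has zero events; an all-censored arm "
                "cannot calibrate a censoring mechanism")
        z, wq = _centred_z_nodes(trial, arm)
        eta = np.exp(linear_predictor(truth, x, z))

        def frac(param: float) -> float:
            return float(np.sum(wq * _event_fraction(mechanism, eta, param)))

        if target >= 1.0:
            param = 0.0 if mechanism == "exponential" else math.inf
        else:
            # monotone in the parameter; bracket then brentq
            if mechanism == "exponential":
                lo, hi = 1e-12, 1.0
                while frac(hi) > target and hi < 1e12:
                    hi *= 10.0
                if frac(hi) > target:
                    raise CalibrationError(
                        f"trial {trial.trial_id}: cannot reach event fraction {target:.4f} "
                        f"in the {arm} arm with exponential censoring (achieved {frac(hi):.4f})")
                param = brentq(lambda p: frac(p) - target, lo, hi, xtol=1e-14, rtol=1e-12)
            else:
                lo, hi = 1e-12, 1.0
                while frac(hi) < target and hi < 1e12:
                    hi *= 10.0
                if frac(hi) < target:
                    raise CalibrationError(
                        f"trial {trial.trial_id}: cannot reach event fraction {target:.4f} "
                        f"in the {arm} arm with {mechanism} censoring (achieved {frac(hi):.4f}); "
                        "the event rate implied by the truth parameters is too low")
                param = brentq(lambda p: frac(p) - target, lo, hi, xtol=1e-14, rtol=1e-12)
        params[arm] = float(param)
        achieved[arm] = frac(param)
        followup[arm] = float(np.sum(wq * _expected_followup(mechanism, eta, param)))
    return CensoringCalibration(mechanism=mechanism, params=params,
                                achieved_event_fraction=achieved, expected_followup=followup)


def simulate_trial(design: SimulationDesign, replicate: int, size: int | None = None,
                   calibration: CensoringCalibration | None = None) -> pd.DataFrame:
    """One synthetic dataset (columns x, z, time, event), deterministic in (seed, replicate).

    ``size`` overrides the trial's sample size (for size sweeps); arm and
    covariate distributions are unchanged. Continuous z is returned centred.
    """
    trial = design.trial
    n = int(size) if size is not None else trial.n
    if calibration is None:
        calibration = calibrate_censoring(trial, design.truth, design.censoring)
    rng = np.random.default_rng([design.seed, int(replicate)])
    cov = trial.covariate
    zbar = trial.pooled_covariate_mean()
    x = (rng.random(n) < trial.prop_treatment).astype(float)
    if cov.kind == "binary":
        p_z = np.where(x == 1, cov.prop_z1_treatment, cov.prop_z1_control)
        z = (rng.random(n) < p_z).astype(float)
    else:
        mean = np.where(x == 1, cov.mean_treatment, cov.mean_control)
        sd = np.where(x == 1, cov.sd_treatment, cov.sd_control)
        z = rng.normal(mean, sd) - zbar
    eta = np.exp(linear_predictor(design.truth, x, z))
    t_event = rng.exponential(1.0 / eta)

    c = np.full(n, np.inf)
    for arm, xi in (("control", 0.0), ("treatment", 1.0)):
        param = calibration.params[arm]
        mask = x == xi
        if not np.isfinite(param):
            continue
        if design.censoring == "uniform_followup":
            c[mask] = rng.uniform(0.0, param, mask.sum())
        elif design.censoring == "fixed_time":
            c[mask] = param
        else:
            if param > 0:
                c[mask] = rng.exponential(1.0 / param, mask.sum())
    time = np.minimum(t_event, c)
    event = (t_event <= c).astype(int)
    time = np.maximum(time, 1e-12)  # guard exact zeros from uniform censoring
    return pd.DataFrame({"x": x, "z": z, "time": time, "event": event})


def se_agreement_study(design: SimulationDesign, scenario: Scenario,
                       options: Sequence[str] = ("i", "ii")) -> pd.DataFrame:
    """Compare aggregate-data approximate SEs with the participant-level ML oracle.

    For each sample size (the trial's n, or ``design.subset_sizes``), simulates
    ``n_replicates`` datasets, fits the exponential model to each, and reports
    the mean model-based SE of the interaction, the empirical SD of the
    interaction estimates across replicates, the approximate SE from each
    requested weight option (scaled from the full-size variance by n/size),
    and the approximation/oracle ratios. Fails if more than 5% of fits fail.
    """
    if design.n_replicates < 50:
        raise ValidationError("se_agreement_study needs n_replicates >= 50 for a stable empirical SD")
    trial = design.trial
    calibration = calibrate_censoring(trial, design.truth, design.censoring)
    sizes = design.subset_sizes or (trial.n,)

    approx_var_full: dict[str, float] = {}
    for opt in options:
        sc = Scenario(lambda_target=scenario.lambda_target, gamma=scenario.gamma,
                      wij_option=opt, alpha=scenario.alpha, mc_size=scenario.mc_size,
                      seed=scenario.seed, expectation_mode=scenario.expectation_mode)
        approx_var_full[opt] = trial_variance(trial, sc).var_lambda

    rows = []
    rep_counter = 0
    for size in sizes:
        lams, ses = [], []
        failures = 0
        for _ in range(design.n_replicates):
            data = simulate_trial(design, rep_counter, size=size, calibration=calibration)
            rep_counter += 1
            try:
                fit: FitResult = fit_mle(data)
            except IPDMAPowerError:
                failures += 1
                continue
            lams.append(fit.params.lam)
            ses.append(math.sqrt(fit.cov[3, 3]))
        if failures > 0.05 * design.n_replicates:
            raise IPDMAPowerError(
                f"size {size}: {failures}/{design.n_replicates} replicate fits failed")
        row = {
            "size": size,
            "n_fits": len(lams),
            "n_failures": failures,
            "mean_model_se": float(np.mean(ses)),
            "empirical_sd": float(np.std(lams, ddof=1)),
        }
        row["sd_over_model_se"] = row["empirical_sd"] / row["mean_model_se"]
        for opt in options:
            se_opt = math.sqrt(approx_var_full[opt] * trial.n / size)
            row[f"approx_se_{opt}"] = se_opt
            row[f"ratio_{opt}"] = se_opt / row["mean_model_se"]
        rows.append(row)
    return pd.DataFrame(rows)
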
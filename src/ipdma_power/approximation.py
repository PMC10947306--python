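"""Approximate each trial's unit information and interaction variance from aggregate data.

The total information of a trial factorises as I = n_eff * I_star, where
I_star = E[w * d d^T] is the expected per-participant ("unit") information
over the joint distribution of treatment assignment x, covariate z and weight
w, with design vector d = (1, x, z, x*z). The variance of the interaction
estimate is then

    var(lam_hat) = [I_star^-1]_(4,4) / n_eff.

Without participant-level data, w = exp(y) * exp(mu_hat) (y the log observed
time) is unknown; three increasingly data-hungry approximations are offered:

option (i)    w = e/n for everyone — equivalently w = 1 with the effective
              sample size set to the event count e. Requires only counts.
option (ii)   exp(y) = the arm's mean follow-up time; exp(mu_hat) built from
              aggregate rates (alpha_hat = log control event rate, beta_hat =
              log rate ratio) plus the assumed prognostic effect gamma and
              interaction lambda. Requires per-arm mean follow-up.
option (iii)  (binary z only) exp(y) = the mean follow-up of the participant's
              (arm, covariate level) subgroup. Requires subgroup follow-ups,
              rarely published.

The covariate is centred by its pooled mean throughout (for option (i) the
interaction variance is invariant to centring; for (ii)/(iii) centring defines
what alpha_hat and beta_hat refer to).

The expectation E[w * d d^T] is evaluated either in closed form (binary z:
a four-cell sum; normal z: exponentially tilted normal moments) or by Monte
Carlo over a large simulated cohort; the two routes agree to MC error and the
analytic route is the default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .aggregate import CovariateSpec, Scenario, TrialAggregate, joint_cell_probabilities
from .errors import (
    ConfigurationError,
    NearSingularWarning,
    UnsupportedCovariateError,
    ValidationError,
)

__all__ = [
    "UnitInformation",
    "TrialVariance",
    "weight_option_i",
    "weight_option_ii",
    "weight_option_iii",
    "unit_information_analytic",
    "unit_information_monte_carlo",
    "unit_information",
    "trial_variance",
    "invert_information",
]

_COND_LIMIT = 1e10


def invert_information(information: np.ndarray) -> np.ndarray:
    """Invert an information matrix, warning when it is near-singular.

    Raises a LinAlgError for an exactly singular matrix and emits
    :class:`NearSingularWarning` when the condition number exceeds 1e10
    (an almost-empty covariate-by-arm cell typically causes this).
    """
    information = np.asarray(information, dtype=float)
    cond = np.linalg.cond(information)
    if not np.isfinite(cond):
        raise np.linalg.LinAlgError("information matrix is singular")
    if cond > _COND_LIMIT:
        warnings.warn(
            f"information matrix nearly singular (condition number {cond:.2e}); "
            "variances may be unstable", NearSingularWarning, stacklevel=2)
    return np.linalg.inv(information)


@dataclass(frozen=True)
class UnitInformation:
    """Expected per-participant information I_star and its effective sample size.

    ``effective_n`` is the divisor turning unit information into the
    interaction variance: the event count e under option (i), the sample size
    n under options (ii)/(iii). ``mc_se_44`` is the Monte Carlo standard error
    of the implied var(lam_hat) (delta method), set only in Monte Carlo mode.
    """

    matrix: np.ndarray
    effective_n: float
    mode: Literal["analytic", "monte_carlo"]
    mc_se_44: float | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValidationError(f"unit information must be 4x4, got {m.shape}")
        if not np.allclose(m, m.T, atol=1e-12, rtol=0.0):
            raise ValidationError("unit information must be symmetric")
        if np.linalg.eigvalsh(m).min() < -1e-10:
            raise ValidationError("unit information must be positive semi-definite")
        if not (self.effective_n > 0):
            raise ValidationError(f"effective_n must be positive, got {self.effective_n}")
        object.__setattr__(self, "matrix", m)

    def variance_of_interaction(self) -> float:
        """var(lam_hat) = [I_star^-1]_(4,4) / effective_n (per covariate unit)."""
        return float(invert_information(self.matrix)[3, 3]) / self.effective_n


@dataclass(frozen=True)
class TrialVariance:
    """var(lam_hat) for one trial, on the per-unit and per-unit_scale covariate scales."""

    trial_id: str
    var_lambda: float
    var_lambda_scaled: float
    option: Literal["i", "ii", "iii"]
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (self.var_lambda > 0):
            raise ValidationError(f"trial {self.trial_id}: var_lambda must be > 0, got {self.var_lambda}")


# ---------------------------------------------------------------------------
# aggregate-data rate estimates shared by options (ii) and (iii)


def _aggregate_rates(trial: TrialAggregate) -> tuple[float, float]:
    """(alpha_hat, beta_hat) from aggregate data, for a participant at the mean covariate:
    alpha_hat = ln(e_C / (n_C f_C)) and beta_hat = ln of the treatment/control rate ratio."""
    if trial.e_control == 0 or trial.e_treatment == 0:
        raise ConfigurationError(
            f"trial {trial.trial_id}: an arm has zero events, so the aggregate event rate is zero "
            "and options (ii)/(iii) are undefined; use option (i) or pool the arms' rates")
    f_c = trial.arm_followup("control")
    f_t = trial.arm_followup("treatment")
    rate_c = trial.e_control / (trial.n_control * f_c)
    rate_t = trial.e_treatment / (trial.n_treatment * f_t)
    return math.log(rate_c), math.log(rate_t / rate_c)


def weight_option_i(trial: TrialAggregate) -> tuple[float, float]:
    """Option (i): w = 1 with effective sample size equal to the event count.

    (Equivalent to w = e/n for everyone with effective size n; the w = 1 form
    keeps the unit information free of an arbitrary common factor.)
    """
    if trial.e < 1:
        raise ConfigurationError(f"trial {trial.trial_id}: no events, no information about the interaction")
    return 1.0, float(trial.e)


def weight_option_ii(trial: TrialAggregate, scenario: Scenario, x, z):
    """Option (ii) weight w(x, z) = f_arm(x) * exp(mu_hat(x, z - z_bar)).

    ``z`` is on the raw covariate scale; centring by the pooled mean happens
    here. Vectorised over x and z.
    """
    alpha_hat, beta_hat = _aggregate_rates(trial)
    lam = scenario.per_unit_lambda(trial.covariate)
    x = np.asarray(x, dtype=float)
    zc = np.asarray(z, dtype=float) - trial.pooled_covariate_mean()
    f_arm = np.where(x == 1, trial.arm_followup("treatment"), trial.arm_followup("control"))
    mu = alpha_hat + beta_hat * x + scenario.gamma * zc + lam * x * zc
    out = f_arm * np.exp(mu)
    return float(out) if out.ndim == 0 else out


def weight_option_iii(trial: TrialAggregate, scenario: Scenario, x, z_level):
    """Option (iii) weight: as option (ii) but exp(y) is the mean follow-up of the
    participant's (arm, binary covariate level) subgroup."""
    if trial.covariate.kind != "binary":
        raise UnsupportedCovariateError(
            f"trial {trial.trial_id}: option (iii) requires a binary covariate")
    alpha_hat, beta_hat = _aggregate_rates(trial)
    lam = scenario.per_unit_lambda(trial.covariate)
    x_arr = np.atleast_1d(np.asarray(x, dtype=float))
    z_arr = np.atleast_1d(np.asarray(z_level, dtype=float))
    x_arr, z_arr = np.broadcast_arrays(x_arr, z_arr)
    exp_y = np.empty(x_arr.shape)
    for xi in (0, 1):
        arm = "treatment" if xi else "control"
        for zi in (0, 1):
            exp_y[(x_arr == xi) & (z_arr == zi)] = trial.subgroup_exp_y(arm, zi)
    zc = z_arr - trial.pooled_covariate_mean()
    mu = alpha_hat + beta_hat * x_arr + scenario.gamma * zc + lam * x_arr * zc
    out = exp_y * np.exp(mu)
    return float(out[0]) if np.isscalar(x) and np.isscalar(z_level) else out.reshape(np.shape(x))


def _effective_n(trial: TrialAggregate, option: str) -> float:
    return float(trial.e) if option == "i" else float(trial.n)


# ---------------------------------------------------------------------------
# analytic expectation


def _design_moment_matrix(x: float, ez: float, ez2: float) -> np.ndarray:
    """E[d d^T] for fixed treatment indicator x, given first two moments of z."""
    return np.array([
        [1.0, x, ez, x * ez],
        [x, x, x * ez, x * ez],
        [ez, x * ez, ez2, x * ez2],
        [x * ez, x * ez, x * ez2, x * ez2],
    ])


def unit_information_analytic(trial: TrialAggregate, scenario: Scenario) -> UnitInformation:
    """Closed-form unit information I_star = E[w * d d^T].

    Binary covariate: a weighted sum over the four (x, z) cells (any option).
    Continuous covariate: per-arm normal moments; options (ii) weights are an
    exponential tilt exp((gamma + lam*x) z) of the arm's normal, handled with
    the tilted-normal identities E[e^{cz}] = e^{cm + c^2 s^2/2} and tilted
    mean m + c s^2 (options (i)/(ii); option (iii) is binary-only).
    """
    option = scenario.wij_option
    cov = trial.covariate
    n_eff = _effective_n(trial, option)

    if cov.kind == "binary":
        cells = joint_cell_probabilities(trial)
        tiny = [k for k, p in cells.items() if p < 1e-6]
        if tiny:
            raise ConfigurationError(
                f"trial {trial.trial_id}: joint cell probability below 1e-6 for (x,z) in {tiny}; "
                "the interaction is not identifiable from this trial's covariate distribution")
        zbar = trial.pooled_covariate_mean()
        I = np.zeros((4, 4))
        for (x, z), p in cells.items():
            if option == "i":
                w = 1.0
            elif option == "ii":
                w = weight_option_ii(trial, scenario, x, z)
            else:
                w = weight_option_iii(trial, scenario, x, z)
            zc = z - zbar
            d = np.array([1.0, x, zc, x * zc])
            I += p * w * np.outer(d, d)
        return UnitInformation(matrix=I, effective_n=n_eff, mode="analytic")

    # continuous (per-arm normal)
    if option == "iii":
        raise UnsupportedCovariateError(
            f"trial {trial.trial_id}: option (iii) requires a binary covariate")
    zbar = trial.pooled_covariate_mean()
    lam = scenario.per_unit_lambda(cov)
    if option == "ii":
        alpha_hat, beta_hat = _aggregate_rates(trial)
    p_t = trial.prop_treatment
    I = np.zeros((4, 4))
    for x, arm_p, arm in ((0.0, 1 - p_t, "control"), (1.0, p_t, "treatment")):
        m = cov.arm_mean(arm) - zbar
        s = cov.sd_control if arm == "control" else cov.sd_treatment
        if option == "i":
            k = 1.0
            c = 0.0
        else:
            c = scenario.gamma + lam * x
            k = trial.arm_followup(arm) * math.exp(alpha_hat + beta_hat * x) \
                * math.exp(c * m + 0.5 * c * c * s * s)
        mt = m + c * s * s  # mean of the tilted normal
        ez, ez2 = mt, s * s + mt * mt
        I += arm_p * k * _design_moment_matrix(x, ez, ez2)
    return UnitInformation(matrix=I, effective_n=n_eff, mode="analytic")


# ---------------------------------------------------------------------------
# Monte Carlo expectation


def unit_information_monte_carlo(trial: TrialAggregate, scenario: Scenario,
                                 rng: np.random.Generator | None = None) -> UnitInformation:
    """Unit information by simulating a large cohort (default one million).

    Samples x ~ Bernoulli(n_T/n), z per arm from the covariate distribution,
    centres z by the population pooled mean (so the estimand matches the
    analytic route exactly), computes w per the scenario's option, and
    averages the per-participant information contributions. Deterministic
    given the scenario seed. ``mc_se_44`` is the delta-method MC standard
    error of the implied interaction variance.
    """
    option = scenario.wij_option
    cov = trial.covariate
    if option == "iii" and cov.kind != "binary":
        raise UnsupportedCovariateError(
            f"trial {trial.trial_id}: option (iii) requires a binary covariate")
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    n = scenario.mc_size
    x = (rng.random(n) < trial.prop_treatment).astype(float)
    if cov.kind == "binary":
        p_z = np.where(x == 1, cov.prop_z1_treatment, cov.prop_z1_control)
        z = (rng.random(n) < p_z).astype(float)
    else:
        mean = np.where(x == 1, cov.mean_treatment, cov.mean_control)
        sd = np.where(x == 1, cov.sd_treatment, cov.sd_control)
        z = rng.normal(mean, sd)

    if option == "i":
        w = np.ones(n)
    elif option == "ii":
        w = weight_option_ii(trial, scenario, x, z)
    else:
        w = weight_option_iii(trial, scenario, x, z)

    zc = z - trial.pooled_covariate_mean()
    D = np.column_stack([np.ones(n), x, zc, x * zc])
    I = (D * w[:, None]).T @ D / n
    n_eff = _effective_n(trial, option)

    # delta-method MC SE of var(lam_hat): linearise the (4,4) inverse element
    u = invert_information(I)[:, 3]
    q = w * (D @ u) ** 2
    se_unit = float(q.std(ddof=1) / math.sqrt(n))  # SE of [I^-1]_44 via -u' dI u
    info = UnitInformation(matrix=(I + I.T) / 2.0, effective_n=n_eff, mode="monte_carlo",
                           mc_se_44=se_unit / n_eff)
    return info


def unit_information(trial: TrialAggregate, scenario: Scenario) -> UnitInformation:
    """Dispatch on the scenario's expectation mode (``auto`` prefers analytic)."""
    mode = scenario.expectation_mode
    if mode == "monte_carlo":
        return unit_information_monte_carlo(trial, scenario)
    return unit_information_analytic(trial, scenario)


def trial_variance(trial: TrialAggregate, scenario: Scenario) -> TrialVariance:
    """var(lam_hat) for one trial from aggregate data alone.

    Returns the variance per single covariate unit and scaled to the
    covariate's ``unit_scale`` (multiplied by unit_scale squared), with the
    option and, for Monte Carlo runs, the seed recorded.
    """
    info = unit_information(trial, scenario)
    var = info.variance_of_interaction()
    scale = trial.covariate.unit_scale
    return TrialVariance(
        trial_id=trial.trial_id,
        var_lambda=var,
        var_lambda_scaled=var * scale * scale,
        option=scenario.wij_option,
        seed=scenario.seed if info.mode == "monte_carlo" else None,
    )
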
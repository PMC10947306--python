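"""Common-effect pooling of per-trial interaction variances and Wald-test power.

Under a common-effect (fixed-effect) two-stage meta-analysis, each trial's
interaction estimate satisfies lam_hat_i ~ N(lam, v_i), and the summary
estimate has variance

    v_pooled = 1 / sum_i (1 / v_i),

with trial weights proportional to 1/v_i. For an assumed true interaction
lam, the two-sided Wald test at level alpha rejects with probability

    power = Phi(-z_{1-alpha/2} + lam/sqrt(v)) + Phi(-z_{1-alpha/2} - lam/sqrt(v)),

which is exactly alpha at lam = 0. The exact normal quantile z_{1-alpha/2}
(1.959964 at alpha = 0.05) is used rather than the conventional 1.96, so the
size of the test is exact; the difference in power is below 1e-5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .aggregate import Scenario, TrialAggregate
from .approximation import TrialVariance, trial_variance
from .errors import IPDMAPowerError, ValidationError

__all__ = [
    "pool_common_effect",
    "trial_weights",
    "wald_power",
    "run_power_analysis",
    "MetaPowerResult",
    "PerTrialResult",
]


def _check_variances(variances: Sequence[float]) -> np.ndarray:
    v = np.asarray(list(variances), dtype=float)
    if v.size == 0:
        raise ValidationError("at least one per-trial variance is required")
    if not np.all(v > 0):
        raise ValidationError(f"all variances must be strictly positive, got {v}")
    return v


def pool_common_effect(variances: Sequence[float]) -> float:
    """Variance of the common-effect summary estimate: 1 / sum(1/v_i)."""
    v = _check_variances(variances)
    return float(1.0 / np.sum(1.0 / v))


def trial_weights(variances: Sequence[float]) -> np.ndarray:
    """Inverse-variance weights as proportions summing to one."""
    v = _check_variances(variances)
    inv = 1.0 / v
    return inv / inv.sum()


def wald_power(lambda_true: float, variance: float, alpha: float = 0.05) -> float:
    """Two-sided Wald power to detect *lambda_true* given the estimate's variance."""
    if not (variance > 0):
        raise ValidationError(f"variance must be > 0, got {variance}")
    if not (0.0 < alpha < 1.0):
        raise ValidationError(f"alpha must lie in (0, 1), got {alpha}")
    z = norm.ppf(1.0 - alpha / 2.0)
    shift = lambda_true / np.sqrt(variance)
    return float(norm.cdf(-z + shift) + norm.cdf(-z - shift))


@dataclass(frozen=True)
class PerTrialResult:
    """One trial's contribution: its variance (both covariate scales), its
    inverse-variance weight, and the power it would have on its own."""

    trial_id: str
    var_lambda: float
    var_lambda_scaled: float
    weight: float
    trial_power: float


@dataclass(frozen=True)
class MetaPowerResult:
    """Pooled variance and power of the planned meta-analysis.

    ``pooled_var`` is per single covariate unit; ``pooled_var_scaled`` per
    ``unit_scale`` units (the scale on which ``lambda_used`` is stated).
    """

    pooled_var: float
    pooled_var_scaled: float
    power: float
    per_trial: tuple[PerTrialResult, ...]
    lambda_used: float
    alpha: float
    option: str

    def __post_init__(self) -> None:
        w = np.array([t.weight for t in self.per_trial])
        if abs(w.sum() - 1.0) > 1e-9 or (w < 0).any():
            raise ValidationError("per-trial weights must be non-negative and sum to 1")
        if self.pooled_var > min(t.var_lambda for t in self.per_trial) * (1 + 1e-12):
            raise ValidationError("pooled variance cannot exceed any per-trial variance")
        if not (0.0 <= self.power <= 1.0):
            raise ValidationError(f"power must lie in [0, 1], got {self.power}")

    def to_dict(self) -> dict:
        return {
            "pooled_var": self.pooled_var,
            "pooled_var_scaled": self.pooled_var_scaled,
            "power": self.power,
            "lambda_used": self.lambda_used,
            "alpha": self.alpha,
            "option": self.option,
            "per_trial": [
                {"trial_id": t.trial_id, "var_lambda": t.var_lambda,
                 "var_lambda_scaled": t.var_lambda_scaled,
                 "weight": t.weight, "trial_power": t.trial_power}
                for t in self.per_trial
            ],
        }


def run_power_analysis(trials: Sequence[TrialAggregate], scenario: Scenario) -> MetaPowerResult:
    """Full pipeline: per-trial variances -> common-effect pooling -> Wald power.

    Also reports, per trial, the power each trial would have standing alone.
    Trials whose variance cannot be computed abort the run with their ids
    (no silent dropping).
    """
    if not trials:
        raise ValidationError("at least one trial is required")
    kinds = {t.covariate.kind for t in trials}
    if len(kinds) > 1:
        raise ValidationError(f"all trials must share one covariate kind, got {sorted(kinds)}")
    scales = {t.covariate.unit_scale for t in trials}
    if len(scales) > 1:
        raise ValidationError(f"all trials must share one covariate unit_scale, got {sorted(scales)}")

    results: list[TrialVariance] = []
    failures: list[str] = []
    for t in trials:
        try:
            results.append(trial_variance(t, scenario))
        except IPDMAPowerError as exc:
            failures.append(f"{t.trial_id}: {exc}")
    if failures:
        raise ValidationError(
            "variance computation failed for trial(s):\n  " + "\n  ".join(failures))

    lam = scenario.per_unit_lambda(trials[0].covariate)
    variances = [r.var_lambda for r in results]
    pooled = pool_common_effect(variances)
    weights = trial_weights(variances)
    scale = trials[0].covariate.unit_scale
    per_trial = tuple(
        PerTrialResult(
            trial_id=r.trial_id,
            var_lambda=r.var_lambda,
            var_lambda_scaled=r.var_lambda_scaled,
            weight=float(w),
            trial_power=wald_power(lam, r.var_lambda, scenario.alpha),
        )
        for r, w in zip(results, weights)
    )
    return MetaPowerResult(
        pooled_var=pooled,
        pooled_var_scaled=pooled * scale * scale,
        power=wald_power(lam, pooled, scenario.alpha),
        per_trial=per_trial,
        lambda_used=scenario.lambda_target,
        alpha=scenario.alpha,
        option=scenario.wij_option,
    )
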
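"""Participant-level exponential survival interaction model.

The model for participant j of a parallel-group trial is

    t_j ~ Exponential(eta_j),    ln eta_j = mu_j = alpha + beta*x_j + gamma*z_j + lam*x_j*z_j

with x the treatment indicator, z the covariate, and lam the
treatment-covariate interaction (the change in treatment log hazard ratio per
unit of z). Equivalently an accelerated-failure-time model
ln t_j = -mu_j + eps_j with extreme-value errors. Censoring enters through the
observed time (minimum of event and censoring time).

The observed information matrix has the closed form

    I = sum_j w_j * d_j d_j^T,   d_j = (1, x_j, z_j, x_j z_j),  w_j = t_j * exp(mu_j)

(with t_j the observed time), whose inverse gives the variance matrix of the
maximum-likelihood estimates; the (4,4) element is var(lam_hat). This module
is the participant-level oracle against which the aggregate-data approximation
engine is validated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

from .errors import ConvergenceError, DesignRankError, DivergenceError, ValidationError

__all__ = [
    "ModelParams",
    "IPDRecord",
    "ipd_frame",
    "linear_predictor",
    "observed_information",
    "variance_of_interaction",
    "log_likelihood",
    "fit_mle",
    "FitResult",
]

_PARAM_NAMES = ("alpha", "beta", "gamma", "lam")
_COLUMN_NAMES = ("intercept", "x", "z", "x*z")


@dataclass(frozen=True)
class ModelParams:
    """(alpha, beta, gamma, lam): log baseline rate, treatment log HR at z=0,
    prognostic log HR per unit z, interaction log HR per unit z."""

    alpha: float
    beta: float = 0.0
    gamma: float = 0.0
    lam: float = 0.0

    def __post_init__(self) -> None:
        vec = self.as_array()
        if not np.all(np.isfinite(vec)):
            raise ValidationError(f"model parameters must be finite, got {vec}")

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma, self.lam], dtype=float)

    @classmethod
    def from_array(cls, v: np.ndarray) -> "ModelParams":
        return cls(*map(float, v))


class IPDRecord(NamedTuple):
    """One participant: treatment indicator, covariate, observed time, event flag."""

    x: float
    z: float
    time: float
    event: int


def ipd_frame(records: Iterable[IPDRecord] | pd.DataFrame) -> pd.DataFrame:
    """Normalise participant-level data to a DataFrame with columns x, z, time, event."""
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records, columns=IPDRecord._fields)
    missing = [c for c in IPDRecord._fields if c not in df.columns]
    if missing:
        raise ValidationError(f"participant data missing column(s): {missing}")
    if not (df["time"].to_numpy() > 0).all():
        raise ValidationError("all observed times must be strictly positive")
    return df


def linear_predictor(params: ModelParams, x, z):
    """Log hazard mu = alpha + beta*x + gamma*z + lam*x*z (vectorised)."""
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    out = params.alpha + params.beta * x + params.gamma * z + params.lam * x * z
    return float(out) if out.ndim == 0 else out


def _design(x: np.ndarray, z: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(x), x, z, x * z])


def _check_rank(D: np.ndarray, w: np.ndarray) -> None:
    """Raise DesignRankError naming the first degenerate column of sqrt(w)*D."""
    W = D * np.sqrt(w)[:, None]
    _, R = np.linalg.qr(W)
    diag = np.abs(np.diag(R))
    scale = diag.max() if diag.max() > 0 else 1.0
    bad = np.nonzero(diag < 1e-10 * scale)[0]
    if bad.size:
        raise DesignRankError(_COLUMN_NAMES[bad[0]])


def observed_information(records, params: ModelParams) -> np.ndarray:
    """4x4 observed information sum_j w_j d_j d_j^T with w_j = time_j * exp(mu_j).

    Requires at least 4 participants and a full-rank design (all four columns
    1, x, z, x*z linearly independent); otherwise raises
    :class:`DesignRankError` naming the degenerate column.
    """
    df = ipd_frame(records)
    if len(df) < 4:
        raise ValidationError(f"need at least 4 participants to identify 4 parameters, got {len(df)}")
    x = df["x"].to_numpy(float)
    z = df["z"].to_numpy(float)
    t = df["time"].to_numpy(float)
    mu = linear_predictor(params, x, z)
    w = t * np.exp(mu)
    D = _design(x, z)
    _check_rank(D, w)
    return (D * w[:, None]).T @ D


def variance_of_interaction(information: np.ndarray) -> float:
    """var(lam_hat): the (4,4) element of the inverse information matrix."""
    from .approximation import invert_information  # shared inversion with conditioning guard

    return float(invert_information(information)[3, 3])


def log_likelihood(records, params: ModelParams) -> float:
    """Exponential/AFT log-likelihood sum_j [event_j * mu_j - time_j * exp(mu_j)]."""
    df = ipd_frame(records)
    mu = linear_predictor(params, df["x"].to_numpy(float), df["z"].to_numpy(float))
    return float(np.sum(df["event"].to_numpy(float) * mu - df["time"].to_numpy(float) * np.exp(mu)))


def _check_separation(x: np.ndarray, z: np.ndarray, ev: np.ndarray, free: np.ndarray) -> None:
    """Raise DivergenceError when a margin identified by a free parameter has no
    events — the classic sufficient condition for an MLE running to -inf."""
    def none_in(mask, label):
        if mask.any() and ev[mask].sum() == 0:
            raise DivergenceError(
                f"no events among participants with {label}: the corresponding log "
                "hazard ratio diverges to -inf (separation)")

    if free[1]:
        none_in(x == 1, "x=1")
        none_in(x == 0, "x=0")
    if set(np.unique(z)) <= {0.0, 1.0}:  # binary covariate: check z margins and cells
        if free[2]:
            none_in(z == 1, "z=1")
            none_in(z == 0, "z=0")
        if free[3]:
            for xi in (0, 1):
                for zi in (0, 1):
                    none_in((x == xi) & (z == zi), f"x={xi}, z={zi}")


class FitResult(NamedTuple):
    params: ModelParams
    cov: np.ndarray          # inverse observed information at the estimate
    loglik: float
    n_iter: int
    grad_norm: float


def fit_mle(records, init: ModelParams | None = None, tol: float = 1e-8,
            max_iter: int = 100, fix: Mapping[str, float] | None = None) -> FitResult:
    """Maximum-likelihood fit by Newton-Raphson with step-halving.

    Convergence is declared when the score max-norm falls below
    ``tol * max(1, total events)`` — the event count is the natural scale of
    the score, so the criterion is sample-size invariant.

    Parameters
    ----------
    records
        Participant-level data (records or DataFrame with x, z, time, event).
    init
        Starting values; defaults to the null model (alpha = ln(total events /
        total time), other parameters 0).
    fix
        Optional map of parameter names to fixed values, e.g.
        ``{"gamma": 0.0, "lam": 0.0}`` fits the two-parameter submodel. The
        returned covariance has rows/columns of fixed parameters set to 0.

    Raises
    ------
    ConvergenceError
        If the gradient max-norm is still above *tol* after *max_iter* steps.
    DivergenceError
        If an estimate runs away to +/-inf (separation, e.g. a covariate cell
        with no events).
    """
    df = ipd_frame(records)
    x = df["x"].to_numpy(float)
    z = df["z"].to_numpy(float)
    t = df["time"].to_numpy(float)
    ev = df["event"].to_numpy(float)
    if ev.sum() < 1:
        raise ValidationError("at least one event is required to fit the model")
    D = _design(x, z)

    fix = dict(fix or {})
    unknown = set(fix) - set(_PARAM_NAMES)
    if unknown:
        raise ValidationError(f"unknown parameter name(s) in fix: {sorted(unknown)}")
    free = np.array([name not in fix for name in _PARAM_NAMES])
    if free.sum() == 0:
        raise ValidationError("at least one parameter must be free")
    _check_rank(D[:, free], np.ones(len(df)))
    _check_separation(x, z, ev, free)

    theta = np.array([np.log(ev.sum() / t.sum()), 0.0, 0.0, 0.0])
    if init is not None:
        theta = init.as_array()
    for name, val in fix.items():
        theta[_PARAM_NAMES.index(name)] = float(val)

    def loglik(th: np.ndarray) -> float:
        mu = D @ th
        return float(np.sum(ev * mu - t * np.exp(mu)))

    ll = loglik(theta)
    grad_norm = np.inf
    for it in range(1, max_iter + 1):
        mu = D @ theta
        if np.max(mu) > 500:  # exp overflow: hazard diverging
            raise DivergenceError("linear predictor diverging; likely separation (a cell with no events)")
        w = t * np.exp(mu)
        grad = D.T @ (ev - w)
        grad_norm = float(np.max(np.abs(grad[free])))
        if grad_norm < tol * max(1.0, float(ev.sum())):
            break
        info = (D[:, free] * w[:, None]).T @ D[:, free]
        try:
            step = np.linalg.solve(info, grad[free])
        except np.linalg.LinAlgError as exc:
            raise DivergenceError(f"information matrix singular during fit: {exc}") from exc
        # step-halving on the log-likelihood
        scale = 1.0
        for _ in range(40):
            cand = theta.copy()
            cand[free] += scale * step
            ll_new = loglik(cand)
            if ll_new >= ll - 1e-12:
                theta, ll = cand, ll_new
                break
            scale *= 0.5
        else:
            raise DivergenceError("step-halving failed to improve the log-likelihood")
        # |log HR| > 20 (HR beyond e^20) can only mean a parameter running to
        # +/-inf, classically a covariate-by-arm cell with no events
        if np.max(np.abs(theta[free])) > 20:
            raise DivergenceError(
                "parameter estimate diverging to +/-inf (separation, e.g. a cell with no events)")
    else:
        raise ConvergenceError(grad_norm, max_iter)

    params = ModelParams.from_array(theta)
    mu = D @ theta
    w = t * np.exp(mu)
    info_free = (D[:, free] * w[:, None]).T @ D[:, free]
    cov = np.zeros((4, 4))
    cov[np.ix_(free, free)] = np.linalg.inv(info_free)
    return FitResult(params=params, cov=cov, loglik=ll, n_iter=it, grad_norm=grad_norm)
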
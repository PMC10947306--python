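"""Per-trial aggregate data: domain types, validation and CSV I/O.

A planned individual-participant-data (IPD) meta-analysis starts from the
published summaries of the candidate trials: participant and event counts per
arm, mean follow-up per arm, and the distribution of the covariate of interest
per arm (a proportion for a binary covariate such as sex; mean and SD for a
continuous covariate such as age, conventionally modelled as normal).
These summaries are what :class:`TrialAggregate` holds, and they are all the
power calculation needs — no participant-level data are required.

The CSV schema (one row per trial) uses percentages for binary covariates,
matching how trial baseline tables report them; internally proportions are
used throughout.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Mapping

import pandas as pd
import yaml

from .errors import ConfigurationError, SchemaError, UnsupportedCovariateError, ValidationError

__all__ = [
    "CovariateSpec",
    "TrialAggregate",
    "Scenario",
    "read_trials",
    "write_trials",
    "joint_cell_probabilities",
    "load_antihypertensive_example",
    "with_subgroup_offsets",
]

Arm = Literal["control", "treatment"]

#: Mandatory CSV columns, in canonical order.
CSV_COLUMNS = [
    "trial_id",
    "n_control",
    "n_treatment",
    "e_control",
    "e_treatment",
    "f_control",
    "f_treatment",
    "cov_kind",
    "cov_prop_z1_control_pct",
    "cov_prop_z1_treatment_pct",
    "cov_mean_control",
    "cov_mean_treatment",
    "cov_sd_control",
    "cov_sd_treatment",
    "cov_unit_scale",
]

#: Optional columns: a covariate name for filtering, and absolute option-(iii)
#: subgroup mean follow-up times per (arm, covariate level).
OPTIONAL_COLUMNS = [
    "covariate",
    "f_control_z0",
    "f_control_z1",
    "f_treatment_z0",
    "f_treatment_z1",
]


@dataclass(frozen=True)
class CovariateSpec:
    """Distribution of the participant-level covariate z, per trial arm.

    Parameters
    ----------
    kind
        ``"binary"`` (z in {0, 1}) or ``"continuous"`` (z normal per arm).
    prop_z1_control, prop_z1_treatment
        Binary only: proportion with z = 1 in each arm, in [0, 1].
    mean_control, mean_treatment, sd_control, sd_treatment
        Continuous only: per-arm normal mean and SD (SD > 0), in covariate units.
    unit_scale
        Covariate increment that one unit of the interaction refers to
        (e.g. 10 for a log hazard ratio "per 10 years of age"). The internal
        per-unit interaction is ``lambda_target / unit_scale``.
    """

    kind: Literal["binary", "continuous"]
    prop_z1_control: float | None = None
    prop_z1_treatment: float | None = None
    mean_control: float | None = None
    mean_treatment: float | None = None
    sd_control: float | None = None
    sd_treatment: float | None = None
    unit_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "continuous"):
            raise ValidationError(f"covariate kind must be 'binary' or 'continuous', got {self.kind!r}")
        if not (self.unit_scale > 0):
            raise ValidationError(f"unit_scale must be > 0, got {self.unit_scale}")
        binary_fields = (self.prop_z1_control, self.prop_z1_treatment)
        cont_fields = (self.mean_control, self.mean_treatment, self.sd_control, self.sd_treatment)
        if self.kind == "binary":
            if any(v is None for v in binary_fields):
                raise ValidationError("binary covariate requires prop_z1_control and prop_z1_treatment")
            if any(v is not None for v in cont_fields):
                raise ValidationError("binary covariate must not set continuous-covariate fields")
            for name in ("prop_z1_control", "prop_z1_treatment"):
                v = getattr(self, name)
                if not (0.0 <= v <= 1.0):
                    raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        else:
            if any(v is None for v in cont_fields):
                raise ValidationError("continuous covariate requires mean and SD for both arms")
            if any(v is not None for v in binary_fields):
                raise ValidationError("continuous covariate must not set binary-covariate fields")
            for name in ("sd_control", "sd_treatment"):
                v = getattr(self, name)
                if not (v > 0):
                    raise ValidationError(f"{name} must be > 0, got {v}")

    # -- convenience constructors -------------------------------------------------

    @classmethod
    def binary(cls, prop_z1_control: float, prop_z1_treatment: float, unit_scale: float = 1.0) -> "CovariateSpec":
        return cls(kind="binary", prop_z1_control=prop_z1_control,
                   prop_z1_treatment=prop_z1_treatment, unit_scale=unit_scale)

    @classmethod
    def binary_overall(cls, prop_z1: float, unit_scale: float = 1.0) -> "CovariateSpec":
        """Covariate summarised only overall: assume the same distribution in both arms
        (legitimate for randomised trials)."""
        return cls.binary(prop_z1, prop_z1, unit_scale)

    @classmethod
    def continuous(cls, mean_control: float, sd_control: float,
                   mean_treatment: float, sd_treatment: float,
                   unit_scale: float = 1.0) -> "CovariateSpec":
        return cls(kind="continuous", mean_control=mean_control, sd_control=sd_control,
                   mean_treatment=mean_treatment, sd_treatment=sd_treatment, unit_scale=unit_scale)

    @classmethod
    def continuous_overall(cls, mean: float, sd: float, unit_scale: float = 1.0) -> "CovariateSpec":
        return cls.continuous(mean, sd, mean, sd, unit_scale)

    def arm_mean(self, arm: Arm) -> float:
        """Mean of z in an arm (for binary, the proportion with z = 1)."""
        if self.kind == "binary":
            return self.prop_z1_control if arm == "control" else self.prop_z1_treatment
        return self.mean_control if arm == "control" else self.mean_treatment


@dataclass(frozen=True)
class TrialAggregate:
    """One trial's published aggregate data.

    ``f_control``/``f_treatment`` are the mean follow-up times (the mean of
    the observed time, whether event or censoring) in consistent time units;
    they are required only for weight options (ii) and (iii).
    ``subgroup_followup`` maps ``(arm, covariate level)`` to the subgroup mean
    follow-up for option (iii); values are absolute unless
    ``subgroup_followup_is_offset`` is set, in which case they are additive
    offsets from the arm mean follow-up.
    """

    trial_id: str
    n_control: int
    n_treatment: int
    e_control: int
    e_treatment: int
    covariate: CovariateSpec
    f_control: float | None = None
    f_treatment: float | None = None
    subgroup_followup: Mapping[tuple[Arm, int], float] | None = None
    subgroup_followup_is_offset: bool = False
    covariate_name: str | None = None

    def __post_init__(self) -> None:
        tid = self.trial_id
        for name in ("n_control", "n_treatment"):
            v = getattr(self, name)
            if not (isinstance(v, (int,)) and v > 0):
                raise ValidationError(f"trial {tid}: {name} must be a positive integer, got {v!r}")
        for name in ("e_control", "e_treatment"):
            v = getattr(self, name)
            if not (isinstance(v, (int,)) and v >= 0):
                raise ValidationError(f"trial {tid}: {name} must be a non-negative integer, got {v!r}")
        if self.e_control > self.n_control:
            raise ValidationError(f"trial {tid}: e_control ({self.e_control}) exceeds n_control ({self.n_control})")
        if self.e_treatment > self.n_treatment:
            raise ValidationError(f"trial {tid}: e_treatment ({self.e_treatment}) exceeds n_treatment ({self.n_treatment})")
        if self.n < 4:
            raise ValidationError(f"trial {tid}: total participants must be >= 4, got {self.n}")
        if self.e < 1:
            raise ValidationError(f"trial {tid}: total events must be >= 1, got {self.e}")
        for name in ("f_control", "f_treatment"):
            v = getattr(self, name)
            if v is not None and not (v > 0):
                raise ValidationError(f"trial {tid}: {name} must be strictly positive when present, got {v}")

    @property
    def n(self) -> int:
        """Total participants."""
        return self.n_control + self.n_treatment

    @property
    def e(self) -> int:
        """Total observed events."""
        return self.e_control + self.e_treatment

    @property
    def prop_treatment(self) -> float:
        """Share of participants randomised to treatment."""
        return self.n_treatment / self.n

    def pooled_covariate_mean(self) -> float:
        """Mean of z pooled across arms — the centring constant."""
        c = self.covariate
        return (self.n_control * c.arm_mean("control")
                + self.n_treatment * c.arm_mean("treatment")) / self.n

    def arm_followup(self, arm: Arm) -> float:
        f = self.f_control if arm == "control" else self.f_treatment
        if f is None:
            raise ConfigurationError(
                f"trial {self.trial_id}: mean follow-up for the {arm} arm is required for "
                "weight options (ii)/(iii); use option (i) if follow-up is unavailable")
        return f

    def subgroup_exp_y(self, arm: Arm, level: int) -> float:
        """Option-(iii) value of exp(y): the (arm, covariate level) subgroup mean follow-up."""
        if self.subgroup_followup is None:
            raise ConfigurationError(
                f"trial {self.trial_id}: option (iii) requires subgroup_followup entries for all "
                "four (arm, level) cells")
        try:
            v = self.subgroup_followup[(arm, level)]
        except KeyError:
            raise ConfigurationError(
                f"trial {self.trial_id}: subgroup_followup is missing the ({arm}, z={level}) entry"
            ) from None
        exp_y = self.arm_followup(arm) + v if self.subgroup_followup_is_offset else v
        if not (exp_y > 0):
            raise ValidationError(
                f"trial {self.trial_id}: subgroup follow-up for ({arm}, z={level}) must be positive, got {exp_y}")
        return exp_y


def with_subgroup_offsets(trial: TrialAggregate, offsets: Mapping[int, float]) -> TrialAggregate:
    """Return a copy of *trial* with option-(iii) subgroup follow-ups given as
    additive offsets from each arm's mean follow-up.

    ``offsets`` maps covariate level (0/1) to the offset in time units, e.g.
    ``{1: -0.25, 0: +0.25}`` for "quarter of a year less follow-up for z = 1,
    quarter more for z = 0" in both arms.
    """
    sub = {(arm, lvl): offsets[lvl] for arm in ("control", "treatment") for lvl in (0, 1)}
    return replace(trial, subgroup_followup=sub, subgroup_followup_is_offset=True)


@dataclass(frozen=True)
class Scenario:
    """Assumptions of one power calculation.

    ``lambda_target`` is the assumed (minimally important) interaction, a log
    hazard ratio per ``unit_scale`` units of the covariate; ``gamma`` is the
    prognostic log hazard ratio per single covariate unit (default 0).
    """

    lambda_target: float
    gamma: float = 0.0
    wij_option: Literal["i", "ii", "iii"] = "i"
    alpha: float = 0.05
    mc_size: int = 1_000_000
    seed: int = 0
    expectation_mode: Literal["analytic", "monte_carlo", "auto"] = "auto"

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.mc_size < 10_000:
            raise ValidationError(f"mc_size must be >= 10000, got {self.mc_size}")
        if self.wij_option not in ("i", "ii", "iii"):
            raise ValidationError(f"wij_option must be one of 'i', 'ii', 'iii', got {self.wij_option!r}")
        if self.expectation_mode not in ("analytic", "monte_carlo", "auto"):
            raise ValidationError(f"unknown expectation_mode {self.expectation_mode!r}")
        if not math.isfinite(self.lambda_target) or not math.isfinite(self.gamma):
            raise ValidationError("lambda_target and gamma must be finite")

    def per_unit_lambda(self, covariate: CovariateSpec) -> float:
        """The interaction per single covariate unit."""
        return self.lambda_target / covariate.unit_scale

    @classmethod
    def from_dict(cls, d: Mapping) -> "Scenario":
        allowed = {"lambda_target", "gamma", "wij_option", "alpha", "mc_size", "seed", "expectation_mode"}
        unknown = set(d) - allowed
        if unknown:
            raise SchemaError(f"unknown scenario fields: {sorted(unknown)}")
        if "lambda_target" not in d:
            raise SchemaError("scenario config must set lambda_target")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "Scenario":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, Mapping):
            raise SchemaError(f"{path}: scenario config must be a mapping")
        return cls.from_dict(data)


# ---------------------------------------------------------------------------
# operations


def joint_cell_probabilities(trial: TrialAggregate) -> dict[tuple[int, int], float]:
    """Joint probabilities Pr(x, z) of treatment arm and binary covariate level.

    Each cell is (arm share of participants) x (within-arm covariate
    proportion); the four cells sum to one. Only defined for binary covariates.
    """
    cov = trial.covariate
    if cov.kind != "binary":
        raise UnsupportedCovariateError(
            f"trial {trial.trial_id}: joint cell probabilities require a binary covariate")
    p_t = trial.prop_treatment
    cells = {
        (0, 1): (1 - p_t) * cov.prop_z1_control,
        (0, 0): (1 - p_t) * (1 - cov.prop_z1_control),
        (1, 1): p_t * cov.prop_z1_treatment,
        (1, 0): p_t * (1 - cov.prop_z1_treatment),
    }
    assert abs(sum(cells.values()) - 1.0) < 1e-12
    return cells


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def _row_to_trial(row: pd.Series, index: int) -> TrialAggregate:
    trial_id = str(row["trial_id"])
    kind = str(row["cov_kind"]).strip().lower()
    unit_scale = _opt_float(row.get("cov_unit_scale"))
    if unit_scale is None:
        unit_scale = 1.0
    if kind == "binary":
        pc = _opt_float(row["cov_prop_z1_control_pct"])
        pt = _opt_float(row["cov_prop_z1_treatment_pct"])
        if pc is None or pt is None:
            raise ValidationError(f"trial {trial_id}: binary covariate requires cov_prop_z1_*_pct")
        cov = CovariateSpec.binary(pc / 100.0, pt / 100.0, unit_scale)
    elif kind == "continuous":
        vals = [_opt_float(row[c]) for c in
                ("cov_mean_control", "cov_sd_control", "cov_mean_treatment", "cov_sd_treatment")]
        if any(v is None for v in vals):
            raise ValidationError(f"trial {trial_id}: continuous covariate requires cov_mean_* and cov_sd_*")
        cov = CovariateSpec.continuous(vals[0], vals[1], vals[2], vals[3], unit_scale)
    else:
        raise ValidationError(f"trial {trial_id}: cov_kind must be 'binary' or 'continuous', got {kind!r}")

    sub = None
    sub_cols = {("control", 0): "f_control_z0", ("control", 1): "f_control_z1",
                ("treatment", 0): "f_treatment_z0", ("treatment", 1): "f_treatment_z1"}
    vals = {k: _opt_float(row.get(c)) for k, c in sub_cols.items()}
    if any(v is not None for v in vals.values()):
        if any(v is None for v in vals.values()):
            raise ValidationError(f"trial {trial_id}: subgroup follow-up columns must be all present or all absent")
        sub = vals

    name = row.get("covariate")
    return TrialAggregate(
        trial_id=trial_id,
        n_control=int(row["n_control"]),
        n_treatment=int(row["n_treatment"]),
        e_control=int(row["e_control"]),
        e_treatment=int(row["e_treatment"]),
        f_control=_opt_float(row["f_control"]),
        f_treatment=_opt_float(row["f_treatment"]),
        covariate=cov,
        subgroup_followup=sub,
        covariate_name=None if name is None or (isinstance(name, float) and math.isnan(name)) else str(name),
    )


def read_trials(path: str | Path, covariate: str | None = None) -> list[TrialAggregate]:
    """Read per-trial aggregate data from CSV; optionally filter by covariate name.

    Row order is preserved. Percentages in the file are converted to
    proportions internally. Raises :class:`SchemaError` for missing columns and
    :class:`ValidationError` for invariant violations (naming trial and field).
    """
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    trials = [_row_to_trial(row, i) for i, (_, row) in enumerate(df.iterrows())]
    if covariate is not None:
        trials = [t for t in trials if t.covariate_name == covariate]
        if not trials:
            raise ConfigurationError(f"{path}: no rows with covariate name {covariate!r}")
    return trials


def write_trials(trials: Iterable[TrialAggregate], path: str | Path) -> None:
    """Write trials back to the CSV schema (inverse of :func:`read_trials`)."""
    rows = []
    for t in trials:
        c = t.covariate
        row = {
            "trial_id": t.trial_id,
            "n_control": t.n_control, "n_treatment": t.n_treatment,
            "e_control": t.e_control, "e_treatment": t.e_treatment,
            "f_control": t.f_control, "f_treatment": t.f_treatment,
            "cov_kind": c.kind,
            "cov_prop_z1_control_pct": None if c.prop_z1_control is None else 100.0 * c.prop_z1_control,
            "cov_prop_z1_treatment_pct": None if c.prop_z1_treatment is None else 100.0 * c.prop_z1_treatment,
            "cov_mean_control": c.mean_control, "cov_mean_treatment": c.mean_treatment,
            "cov_sd_control": c.sd_control, "cov_sd_treatment": c.sd_treatment,
            "cov_unit_scale": c.unit_scale,
            "covariate": t.covariate_name,
        }
        if t.subgroup_followup is not None and not t.subgroup_followup_is_offset:
            row.update({
                "f_control_z0": t.subgroup_followup[("control", 0)],
                "f_control_z1": t.subgroup_followup[("control", 1)],
                "f_treatment_z0": t.subgroup_followup[("treatment", 0)],
                "f_treatment_z1": t.subgroup_followup[("treatment", 1)],
            })
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def load_antihypertensive_example(covariate: Literal["sex", "age"] = "sex") -> list[TrialAggregate]:
    """The packaged 10-trial anti-hypertensive example, with either sex
    (binary; z = 1 for male; interaction per unit) or age (continuous; per-arm
    normal; interaction per 10 years) as the covariate of interest."""
    ref = resources.files("ipdma_power").joinpath("data/antihypertensive_table1.csv")
    with resources.as_file(ref) as p:
        return read_trials(p, covariate=covariate)
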
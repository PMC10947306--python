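"""Exception hierarchy.

All package-specific failures derive from :class:`IPDMAPowerError` so callers
can catch one type at the CLI boundary.
"""


class IPDMAPowerError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(IPDMAPowerError):
    """An input file does not conform to the documented column schema."""


class ValidationError(IPDMAPowerError):
    """A value violates a domain invariant (names the trial and field)."""


class UnsupportedCovariateError(IPDMAPowerError):
    """Operation requested for a covariate kind it does not support."""


class ConfigurationError(IPDMAPowerError):
    """Scenario/option combination is inconsistent with the available data."""


class DesignRankError(IPDMAPowerError):
    """Design matrix is rank deficient; carries the degenerate column name."""

    def __init__(self, column: str, message: str | None = None):
        self.column = column
        super().__init__(message or f"design matrix is rank deficient: column '{column}' is degenerate")


class ConvergenceError(IPDMAPowerError):
    """Iterative fit failed to converge; carries the last gradient norm."""

    def __init__(self, grad_norm: float, n_iter: int):
        self.grad_norm = grad_norm
        self.n_iter = n_iter
        super().__init__(
            f"Newton-Raphson did not converge after {n_iter} iterations "
            f"(max |gradient| = {grad_norm:.3e})"
        )


class DivergenceError(IPDMAPowerError):
    """A parameter is diverging to +/-inf (e.g. separation: a cell with no events)."""


class CalibrationError(IPDMAPowerError):
    """Censoring calibration target is infeasible for the chosen mechanism."""


class NearSingularWarning(UserWarning):
    """Information matrix is numerically close to singular."""
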
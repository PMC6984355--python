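"""Exception hierarchy for model specification, estimation and input errors."""


class MbcoError(Exception):
    """Base class for all package-specific errors."""


class ModelSpecificationError(MbcoError, ValueError):
    """The path model is structurally invalid (cycle, unknown label, ...)."""


class InputDataError(MbcoError, ValueError):
    """The data table cannot be used (missing columns, NaNs, non-numeric)."""


class EstimationError(MbcoError, RuntimeError):
    """Maximum-likelihood estimation failed (rank deficiency, degenerate fit)."""


class ConvergenceError(EstimationError):
    """No optimizer start converged to a feasible constrained optimum."""


class InternalConsistencyError(MbcoError, RuntimeError):
    """A nesting/feasibility invariant was violated (null LL above full LL)."""


class InfeasibleMomentsError(MbcoError, ValueError):
    """Requested skewness/kurtosis pair is outside the Fleishman-feasible region."""
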
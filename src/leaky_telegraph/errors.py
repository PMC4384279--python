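"""Exception hierarchy shared by all modules."""


class LeakyTelegraphError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(LeakyTelegraphError, ValueError):
    """A kinetic parameter violates its admissibility constraints."""


class DegenerateParameterError(LeakyTelegraphError, ValueError):
    """The analytic solution is undefined for this parameter set.

    Raised when the constant R = (lambda1 - lambda0) - f*lambda0 is too
    close to zero, where alpha diverges.  Callers should use the
    chemical-master-equation solver (``leaky_telegraph.cme``) instead.
    """


class NumericalError(LeakyTelegraphError, ArithmeticError):
    """A numerical evaluation failed to reach the required accuracy."""


class DomainError(LeakyTelegraphError, ValueError):
    """An argument lies outside the mathematical domain of a function."""


class TruncationError(LeakyTelegraphError, RuntimeError):
    """State-space truncation could not confine the stationary mass."""


class InsufficientDataError(LeakyTelegraphError, RuntimeError):
    """A trajectory does not contain enough events for the estimator."""


class InfeasiblePointError(LeakyTelegraphError, RuntimeError):
    """No nonnegative compensating parameter attains the target mean."""


class UnsupportedRegimeError(LeakyTelegraphError, ValueError):
    """The closed-form result is not stated for this parameter regime."""


class ConfigurationError(LeakyTelegraphError, ValueError):
    """A configuration value (variant tag, file key, ...) is unknown."""
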
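"""Exception types shared across the package."""


class GroupslopeError(Exception):
    """Base class for all package-specific errors."""


class UnbalancedDataError(GroupslopeError):
    """Raised when an operation requires balanced groups (equal group sizes)."""


class DegenerateGroupError(GroupslopeError):
    """Raised when a group has fewer than two members."""


class DegenerateVarianceError(GroupslopeError):
    """Raised when the between-group variance estimate is exactly zero,
    making the ML slope undefined (division by zero)."""


class InvalidPriorError(GroupslopeError):
    """Raised when a prior/variance combination yields a non-positive
    shrinkage denominator."""


class UndefinedMomentError(GroupslopeError):
    """Raised when a requested moment of the approximating distribution does
    not exist (denominator degrees of freedom too small).

    Attributes
    ----------
    df : float
        The offending denominator degrees of freedom (2 * matched gamma shape).
    """

    def __init__(self, message: str, df: float):
        super().__init__(message)
        self.df = df


class InfeasibleParamsError(GroupslopeError):
    """Raised when no nonnegative residual-variance solution exists for a
    requested (icc_x, icc_y, beta_b, beta_w) configuration.

    Attributes
    ----------
    constraint : str
        Name of the binding constraint.
    """

    def __init__(self, message: str, constraint: str):
        super().__init__(message)
        self.constraint = constraint


class BalanceAbortedError(GroupslopeError):
    """Raised when balancing would delete more than the allowed fraction of
    rows.  Carries the :class:`~groupslope.balance.BalanceReport`."""

    def __init__(self, message: str, report):
        super().__init__(message)
        self.report = report
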
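"""Exception types raised across the package."""


class ThiodoseError(Exception):
    """Base class for package errors."""


class InvalidActivityError(ThiodoseError, ValueError):
    """TPMT activity outside its physical range (0 <= e <= e_max, e_max > 0)."""


class IntegrationError(ThiodoseError, RuntimeError):
    """ODE solver failed; carries the solver diagnostic message."""


class InfeasibleSteadyStateError(ThiodoseError, ValueError):
    """No non-negative steady state exists for the requested infusion."""


class LikelihoodError(ThiodoseError, ValueError):
    """Model prediction non-finite or error variance degenerate."""


class EmptyGroupError(ThiodoseError, ValueError):
    """No patient falls in the requested TPMT activity window."""


class InfeasibleControlError(ThiodoseError, ValueError):
    """Dose bounds and slew constraints admit no feasible plan."""
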
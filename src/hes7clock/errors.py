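"""Exception types shared across the package."""


class Hes7ClockError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(Hes7ClockError, ValueError):
    """A model or gene-architecture parameter violates its constraints."""


class InvalidInputError(Hes7ClockError, ValueError):
    """A data input (trajectory, series, sample set) violates its contract."""


class IntegrationAccuracyError(Hes7ClockError, RuntimeError):
    """The integrator produced a state inconsistent with the model's
    invariants (e.g. a negative concentration beyond round-off), indicating
    the step size is too large for the requested problem."""
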
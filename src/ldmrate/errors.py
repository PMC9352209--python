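"""Exception types shared across the package."""


class LdmError(Exception):
    """Base class for all ldmrate errors."""


class DomainError(LdmError, ValueError):
    """An argument is outside the mathematical domain of the operation."""


class NoEventError(LdmError):
    """The conjugation hazard is identically zero: no first event exists."""


class IntegrationError(LdmError):
    """Numerical integration of the mating model failed.

    Carries the time reached before the state became nonfinite.
    """

    def __init__(self, message: str, t_reached: float | None = None):
        super().__init__(message)
        self.t_reached = t_reached


class SimulationError(LdmError):
    """A stochastic run could not be completed (e.g. propensity overflow)."""


class PlateParseError(LdmError, ValueError):
    """A plate CSV file violated the documented dialect.

    ``violations`` lists every problem found, each prefixed with the
    offending line number where available.
    """

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__(
            "invalid plate file:\n  " + "\n  ".join(self.violations)
        )
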
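"""Exception types shared across the package."""


class OpnCircuitError(Exception):
    """Base class for all package errors."""


class InvalidScheduleError(OpnCircuitError):
    """Relapse schedule has negative durations or inconsistent window."""


class IntegrationError(OpnCircuitError):
    """ODE solver failed; carries the time at which integration stopped."""

    def __init__(self, message: str, t_fail: float | None = None):
        super().__init__(message)
        self.t_fail = t_fail


class DegenerateMeasurementError(OpnCircuitError):
    """Cohort measurements make a closed-form derivation singular."""


class InadmissibleParameterError(OpnCircuitError):
    """A derived rate constant violates its sign constraint."""


class UndefinedGammaError(OpnCircuitError):
    """Relapse multiplier cannot be derived (x_t = 0)."""


class UndefinedIndexError(OpnCircuitError):
    """Chemotactic index undefined (zero stimulus concentration)."""


class SingularSystemError(OpnCircuitError):
    """Fragment exposure integral is zero; migration cannot be attributed."""


class UndefinedR2Error(OpnCircuitError):
    """Outcome is constant; coefficient of determination undefined."""


class MissingReferenceError(OpnCircuitError):
    """No normative assessments for the queried disease duration."""
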
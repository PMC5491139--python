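"""Exception hierarchy shared across the package."""


class QuorumClockError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(QuorumClockError, ValueError):
    """An argument violates a documented precondition."""


class NoOscillationError(QuorumClockError):
    """A trace did not contain enough peaks to define a period or phase."""


class CalibrationError(QuorumClockError):
    """Time-scale calibration failed because the isolated cell does not oscillate."""


class IntegrationError(QuorumClockError):
    """Numerical integration failed; carries the time and cell index if known."""

    def __init__(self, message: str, time: float | None = None, cell: int | None = None):
        super().__init__(message)
        self.time = time
        self.cell = cell


class ConfigError(QuorumClockError):
    """A configuration file is malformed; carries the offending key if known."""

    def __init__(self, message: str, key: str | None = None):
        super().__init__(message)
        self.key = key
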
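"""Exception hierarchy shared across the package."""


class EcocultureError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(EcocultureError, ValueError):
    """A model, forcing or analysis parameter violates its constraints."""


class DegenerateStateError(EcocultureError, ValueError):
    """The effective carrying capacity K(1+c) became non-positive while the
    population was still alive, so the logistic growth target is undefined."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


class IntegrationError(EcocultureError, RuntimeError):
    """A state variable became non-finite during time stepping."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


class UndefinedPhaseError(EcocultureError, ValueError):
    """Instantaneous phase is undefined (e.g. constant input series)."""


class InsufficientDataError(EcocultureError, ValueError):
    """Too few samples for the requested statistic."""


class ConfigError(EcocultureError, ValueError):
    """Configuration file violates the schema."""
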
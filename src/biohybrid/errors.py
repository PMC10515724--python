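"""Exception hierarchy shared across the package."""


class BiohybridError(Exception):
    """Base class for all package errors."""


class ContractError(BiohybridError, ValueError):
    """A caller violated an interface contract (shapes, missing inputs, ...)."""


class InvalidStateError(BiohybridError, ValueError):
    """A physical state is invalid (e.g. non-positive culture volume)."""


class DivergenceError(BiohybridError, ArithmeticError):
    """Numerical integration produced NaN/Inf; carries the failing time."""

    def __init__(self, t: float, message: str | None = None):
        self.t = float(t)
        super().__init__(message or f"integration diverged at t={t:g} h")


class SchemaError(BiohybridError, ValueError):
    """A dataset file violated the on-disk schema; names the offending cell."""


class GenerationError(BiohybridError, RuntimeError):
    """The synthetic-data generator produced an unusable trajectory."""


class TrainingError(BiohybridError, RuntimeError):
    """Training could not proceed (e.g. repeated non-finite gradients)."""


class DomainError(BiohybridError, ValueError):
    """A statistic was requested outside its mathematical domain."""
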
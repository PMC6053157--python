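"""Exception hierarchy for the viscometry / velocimetry / imaging pipeline."""


class HemorheoError(Exception):
    """Base class for all package errors."""


class DomainError(HemorheoError, ValueError):
    """An input is outside the physical or mathematical domain of an operation."""


class ConvergenceError(HemorheoError, RuntimeError):
    """A truncated series or iterative solver failed to converge.

    Carries the last two partial values so the caller can judge how far
    from convergence the computation stopped.
    """

    def __init__(self, message, last_values=None):
        super().__init__(message)
        self.last_values = last_values


class InversionError(HemorheoError, RuntimeError):
    """A root bracket for an inverse problem contains no solution."""

    def __init__(self, message, bracket_values=None):
        super().__init__(message)
        self.bracket_values = bracket_values


class FitError(HemorheoError, RuntimeError):
    """A model fit failed; carries best-so-far parameters when available."""

    def __init__(self, message, best_params=None, residual=None):
        super().__init__(message)
        self.best_params = best_params
        self.residual = residual


class DetectionError(HemorheoError, RuntimeError):
    """A detection step (layer boundary, threshold) found nothing usable."""


class ConfigurationError(HemorheoError, ValueError):
    """Invalid configuration of an operation (bad bins, single frame, ...)."""
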
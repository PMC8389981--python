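"""Exception hierarchy.

``ZeroIonicStrengthError`` is deliberately distinct from the generic
``InvalidConditionsError`` so that callers can tell "no electrolyte, Debye
length undefined" apart from malformed inputs.
"""


class NanoshsError(Exception):
    """Base class for all package errors."""


class InvalidConditionsError(NanoshsError, ValueError):
    """A domain object violates one of its invariants."""


class ZeroIonicStrengthError(NanoshsError, ValueError):
    """Debye screening requested at zero (or negative) electrolyte
    concentration, where the Debye length diverges."""


class InversionError(NanoshsError, RuntimeError):
    """Numerical inversion of a charge-potential relation failed; carries
    bracketing diagnostics."""

    def __init__(self, message: str, *, sigma=None, bracket=None):
        super().__init__(message)
        self.sigma = sigma
        self.bracket = bracket


class FitConvergenceError(NanoshsError, RuntimeError):
    """Nonlinear least squares did not converge; ``best_params`` holds the
    best parameter vector seen."""

    def __init__(self, message: str, *, best_params=None):
        super().__init__(message)
        self.best_params = best_params


class CsvFormatError(NanoshsError, ValueError):
    """A titration CSV violates the dialect; ``row`` is the offending
    1-based data row where applicable."""

    def __init__(self, message: str, *, row=None):
        super().__init__(message)
        self.row = row


class ConfigError(NanoshsError, ValueError):
    """Analysis configuration failed validation."""
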
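"""Exception hierarchy shared across the package."""


class CanemetricsError(Exception):
    """Base class for all package errors."""


class FormatError(CanemetricsError):
    """A campaign file is structurally unreadable (missing columns, bad header)."""


class DomainError(CanemetricsError, ValueError):
    """An input violates a physical or mathematical precondition."""


class InputError(CanemetricsError, ValueError):
    """An input has the wrong shape/size for the requested operation."""


class ConfigurationError(CanemetricsError):
    """A configuration value is missing or inconsistent."""


class FitError(CanemetricsError):
    """A model fit failed to converge.

    Carries optimizer diagnostics in :attr:`diagnostics`.
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class EnsembleError(CanemetricsError):
    """Too many replicate fits of a perturbation ensemble failed."""

    def __init__(self, message, n_failed=0, n_total=0, diagnostics=None):
        super().__init__(message)
        self.n_failed = n_failed
        self.n_total = n_total
        self.diagnostics = diagnostics or {}
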
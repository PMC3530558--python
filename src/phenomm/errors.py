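"""Exception hierarchy shared across the package."""


class PhenommError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PhenommError):
    """A run or column configuration is incomplete or inconsistent."""


class ValidationError(PhenommError):
    """Input data violates a declared contract (bad label, out-of-range value)."""


class InsufficientDataError(PhenommError):
    """Too few records, groups or batches to carry out the requested operation."""


class FittingError(PhenommError):
    """Model fitting failed to converge; carries optimizer diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
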
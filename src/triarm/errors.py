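"""Exception hierarchy shared across the pipeline stages."""


class TriarmError(Exception):
    """Base class for all package-specific errors."""


class DesignError(TriarmError):
    """Invalid trial design input (wrong cluster count, duplicate ids, ...)."""


class GenerationError(TriarmError):
    """The generative parameters imply an invalid Bernoulli risk (p >= 1)."""


class DataError(TriarmError):
    """Malformed person-week or analysis-row data."""


class ModelDesignError(TriarmError):
    """Design matrix cannot be built (unseen level, rank deficiency, ...)."""


class ConvergenceError(TriarmError):
    """MCMC diagnostics failed (R-hat too large or effective sample too small)."""

    def __init__(self, message: str, offending: dict | None = None):
        super().__init__(message)
        self.offending = offending or {}


class TruncationError(TriarmError):
    """Predictive-margin truncation rate exceeded the strict-mode limit."""


class ConfigError(TriarmError):
    """Invalid pipeline configuration."""
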
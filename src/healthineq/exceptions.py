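"""Exception types shared across the package."""


class HealthineqError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HealthineqError, ValueError):
    """A configuration object or file is internally inconsistent."""


class ValidationError(HealthineqError, ValueError):
    """Input data violate a precondition (negative counts, bad codes, ...)."""


class DegenerateRankingError(HealthineqError, ValueError):
    """The equity stratifier has fewer than two observed categories; the
    concentration index is undefined on a single-group ranking."""


class UndefinedIndexError(HealthineqError, ZeroDivisionError):
    """The index cannot be computed (zero prevalence, or zero outcome
    concentration index when percent contributions are requested)."""


class FitError(HealthineqError, RuntimeError):
    """The outcome regression failed to converge even after a ridge-stabilized
    restart; carries diagnostics in ``args``."""


class DesignError(HealthineqError, ValueError):
    """The survey design is unusable for the requested variance method
    (e.g. a stratum with a single cluster under the bootstrap)."""
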
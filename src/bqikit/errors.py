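"""Exception hierarchy shared across the package."""


class BqikitError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(BqikitError):
    """A delimited-text input violates the expected schema or an invariant."""


class ResolutionError(BqikitError):
    """A recall line references a food id absent from the library."""


class DomainError(BqikitError):
    """A value is outside the domain an operation is defined on."""


class ReferenceLookupError(BqikitError):
    """A sex/age stratum is missing from a reference table."""


class FitError(BqikitError):
    """A regression cannot be fitted (rank deficiency, too few cases, degenerate stratum)."""


class ConfigError(BqikitError):
    """A generator configuration is invalid or infeasible."""
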
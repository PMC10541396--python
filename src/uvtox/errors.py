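"""Exception hierarchy shared by the pipeline stages."""


class UvtoxError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(UvtoxError):
    """An input table does not match the documented column set."""


class ValidationError(UvtoxError):
    """Input rows violate a domain invariant (units, count pairing, ...)."""


class DomainError(UvtoxError):
    """An argument is outside the mathematical domain of an operation."""


class DegenerateDesignError(UvtoxError):
    """The regression design is singular (e.g. one distinct concentration)."""


class NoResponseError(UvtoxError):
    """No usable response in the series (e.g. all gamma values zero)."""


class ConfigError(UvtoxError):
    """An option combination is inconsistent (e.g. inverted additive band)."""
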
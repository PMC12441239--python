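"""Exception hierarchy shared across the package."""


class StandCarbonError(Exception):
    """Base class for all package errors."""


class FormatError(StandCarbonError):
    """A file does not conform to the expected delimited-text schema."""


class ValidationError(StandCarbonError):
    """Input data violate a domain invariant (bounds, uniqueness, signs)."""


class ConfigurationError(StandCarbonError):
    """A configuration value is inconsistent or out of its valid range."""
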
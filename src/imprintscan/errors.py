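"""Exception hierarchy shared across the package."""


class ImprintscanError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ImprintscanError):
    """A file does not conform to the expected layout."""


class ValidationError(ImprintscanError):
    """Data violate a domain invariant (range, uniqueness, vocabulary)."""


class ConfigError(ImprintscanError):
    """A configuration value is missing or out of range."""


class UndefinedValueError(ImprintscanError):
    """A quantity is mathematically undefined for the given input."""


class MendelianInconsistencyError(ImprintscanError):
    """A child genotype is impossible given the maternal genotype."""
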
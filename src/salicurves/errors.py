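"""Exception hierarchy shared across the package."""


class SaliError(Exception):
    """Base class for all salicurves errors."""


class ConfigurationError(SaliError):
    """A required configuration entry (column name, path, option) is missing or invalid."""


class ParseError(SaliError):
    """An input file could not be parsed into valid records."""


class ValidationError(SaliError):
    """Parsed data violates a structural invariant (duplicate ids, asymmetry, range)."""


class DegenerateInputError(SaliError):
    """The requested statistic is undefined on this input (no eligible pairs, constant vector, empty edge set)."""
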
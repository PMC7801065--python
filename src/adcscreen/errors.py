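"""Exception hierarchy."""


class AdcScreenError(Exception):
    """Base class for all package errors."""


class ParseError(AdcScreenError):
    """A file could be opened but its content is not in the expected dialect."""


class SchemaError(AdcScreenError):
    """A table is missing a required column."""


class ValidationError(AdcScreenError):
    """Parsed content violates a domain invariant (negative count, duplicate id, ...)."""


class ConfigError(AdcScreenError):
    """A configuration value is out of range or inconsistent."""


class DegenerateDataError(AdcScreenError):
    """A statistic is undefined on the given input (zero variance, excluded core, ...)."""
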
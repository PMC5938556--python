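"""Exception hierarchy shared by all pipeline stages."""


class DustairError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(DustairError):
    """A configuration value is invalid or internally inconsistent."""


class DataError(DustairError):
    """Input data violate a structural requirement (ids, dimensions, domains)."""


class ParseError(DataError):
    """A file could not be parsed; the message names the offending cell/field."""
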
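"""Exception hierarchy.

``ValidationError`` maps to CLI exit code 2, every other
``MosaicscanError`` to exit code 1.
"""


class MosaicscanError(Exception):
    """Base class for all package errors."""


class ValidationError(MosaicscanError):
    """Invalid inputs, preconditions, or configuration values."""


class ParseError(ValidationError):
    """A file could not be parsed."""


class ConfigurationError(ValidationError):
    """A configuration value is missing or inconsistent."""
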
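"""Exception hierarchy.

``ConfigError`` marks invalid user-supplied parameters or configuration,
``DataError`` marks malformed or inconsistent input data, and
``ATCFormatError`` marks a string that is not a valid ATC code. The CLI
maps these to distinct exit codes (2 for configuration, 3 for data).
"""


class ComedclustError(Exception):
    """Base class for all errors raised by comedclust."""


class ConfigError(ComedclustError, ValueError):
    """Invalid configuration or parameter value."""


class DataError(ComedclustError, ValueError):
    """Malformed, inconsistent, or out-of-contract input data."""


class ATCFormatError(DataError):
    """A string that does not follow the ATC code grammar."""
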
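"""Exception hierarchy.

``InputError`` marks bad data (malformed files, empty groups, unknown ids);
``ConfigError`` marks invalid parameters. The CLI maps them to exit codes
1 and 2 respectively.
"""


class StratomicsError(Exception):
    """Base class for all package errors."""


class InputError(StratomicsError):
    """Invalid or inconsistent input data."""


class ConfigError(StratomicsError):
    """Invalid configuration or parameter value."""
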
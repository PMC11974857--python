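"""Exception hierarchy shared across the pipeline.

Errors are split by who can fix them: ``ConfigError`` for a bad
configuration file or parameter set, ``DataError`` for malformed or
degenerate input data. The CLI maps them to exit codes 2 and 3.
"""


class RhodoflagError(Exception):
    """Base class for all package errors."""


class ConfigError(RhodoflagError):
    """Invalid configuration (bad key, out-of-range value)."""


class DataError(RhodoflagError):
    """Invalid or degenerate input data."""
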
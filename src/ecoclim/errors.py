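"""Exception hierarchy shared across the pipeline.

``ConfigError`` maps to CLI exit code 2, ``DataError`` to exit code 3.
"""


class EcoclimError(Exception):
    """Base class for all package errors."""


class ConfigError(EcoclimError):
    """Invalid configuration: bad parameter file, missing section, bad value."""


class DataError(EcoclimError):
    """Invalid or inconsistent data: geometry mismatch, missing layer, shortfall."""
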
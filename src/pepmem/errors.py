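"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: ConfigError -> 2, DataError -> 3,
NumericalError -> 4.
"""


class PepmemError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(PepmemError, ValueError):
    """Invalid configuration, parameters, or preconditions."""


class DataError(PepmemError, ValueError):
    """Malformed, inconsistent, or insufficient input data."""


class NumericalError(PepmemError, RuntimeError):
    """A numerical procedure failed to converge or produced invalid output."""
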
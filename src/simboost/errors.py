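"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: ConfigError -> 1, DataFormatError -> 2,
NumericalError -> 3.
"""


class SimBoostError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(SimBoostError):
    """Invalid configuration or parameter value."""


class DataFormatError(SimBoostError):
    """Malformed or inconsistent input data."""


class NumericalError(SimBoostError):
    """Numerical failure (divergence, non-convergence)."""
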
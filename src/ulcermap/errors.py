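"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: configuration problems exit 2, data
problems exit 3, and iterative solvers that fail to converge exit 4.
"""


class UlcermapError(Exception):
    """Base class for all package errors."""


class ConfigurationError(UlcermapError):
    """Invalid configuration value or malformed config file."""


class DataError(UlcermapError):
    """Input data violates a precondition (missing genes, empty groups...)."""


class ConvergenceError(UlcermapError):
    """An iterative solver exhausted its iteration budget."""
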
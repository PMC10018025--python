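"""Exception hierarchy mapped to CLI exit codes."""


class CortexlinkError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(CortexlinkError):
    """Invalid configuration or parameters (exit code 2)."""

    exit_code = 2


class DataError(CortexlinkError):
    """Malformed, inconsistent or missing input data (exit code 3)."""

    exit_code = 3


class NumericalError(CortexlinkError):
    """Numerical failure: rank deficiency, singular covariance, etc. (exit code 4)."""

    exit_code = 4
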
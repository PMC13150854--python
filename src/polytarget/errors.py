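"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError -> 3.
"""


class PolytargetError(Exception):
    """Base class for all package errors."""


class ConfigError(PolytargetError):
    """Invalid configuration, unknown option value, missing input file."""


class DataError(PolytargetError):
    """Malformed or inconsistent input data (record-level problems)."""


class ConvergenceError(PolytargetError):
    """An iterative fit failed to converge; carries the log-likelihood trace."""

    def __init__(self, message, loglik_trace=None):
        super().__init__(message)
        self.loglik_trace = list(loglik_trace) if loglik_trace is not None else []
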
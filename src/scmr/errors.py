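"""Exception hierarchy mapped to CLI exit codes."""


class ScmrError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(ScmrError):
    """Invalid configuration value or unknown configuration key."""

    exit_code = 2


class InputError(ScmrError):
    """Malformed or inconsistent input data."""

    exit_code = 3


class EstimationError(ScmrError):
    """An estimator cannot be computed from the given instruments."""

    exit_code = 4
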
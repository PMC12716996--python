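"""Exception hierarchy. Exit codes used by the CLI are attached per class."""


class FstkitError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(FstkitError):
    """Invalid configuration value; message names the offending field."""

    exit_code = 2


class ValidationError(FstkitError):
    """Malformed state or mismatched inputs."""

    exit_code = 3


class DomainError(ValidationError):
    """Argument outside the mathematical domain of an operation."""

    exit_code = 3


class MeasureInfeasibleError(FstkitError):
    """A measure cannot be applied (e.g. staple compensation would go negative)."""

    exit_code = 4


class UnknownMeasureError(FstkitError):
    """Unrecognised measure name; message lists the valid names."""

    exit_code = 2
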
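"""Exception hierarchy mapped onto CLI exit codes."""


class PhenocellError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(PhenocellError):
    """Invalid or inconsistent configuration."""

    exit_code = 2


class DataValidationError(PhenocellError):
    """Input data violates a structural invariant."""

    exit_code = 3


class MissingArtifactError(PhenocellError):
    """A required upstream stage output is absent."""

    exit_code = 4
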
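"""Exception hierarchy shared across the package."""


class ThyrosigError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ThyrosigError):
    """Invalid parameters, scenarios, groups or pipeline configuration."""


class DataError(ThyrosigError):
    """Structurally valid input whose content violates a precondition."""


class ParseError(ThyrosigError):
    """Malformed tabular input.

    Carries the 1-based data row number when it can be located.
    """

    def __init__(self, message: str, row: int | None = None):
        if row is not None:
            message = f"{message} (row {row})"
        super().__init__(message)
        self.row = row


class PipelineStageError(ThyrosigError):
    """A pipeline stage failed; names the stage and chains the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
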
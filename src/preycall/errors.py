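"""Exception types shared across the pipeline.

Every error raised by preycall derives from :class:`PreycallError` so callers
(and the CLI) can catch pipeline failures distinctly from programming errors.
"""


class PreycallError(Exception):
    """Base class for all preycall errors."""


class ParameterError(PreycallError, ValueError):
    """An invalid configuration or threshold value; names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class PsmValidationError(PreycallError, ValueError):
    """A malformed PSM record; carries the offending row index."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"PSM row {row}: {message}")


class InsufficientReplicatesError(PreycallError, ValueError):
    """Fewer than two replicate values in a group."""


class UndefinedEstimateError(PreycallError, ValueError):
    """An estimator was asked for on an empty table."""


class MatrixMismatchError(PreycallError, ValueError):
    """Raw and normalized matrices do not share proteins/samples, or flags are wrong."""


class StageError(PreycallError, RuntimeError):
    """A pipeline stage failed; names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
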
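"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ConfigurationError -> 2, DataError and
its subclasses -> 3, StageError -> 4.
"""


class PmfCountError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PmfCountError):
    """Invalid or inconsistent configuration (unknown keys, bad values)."""


class DataError(PmfCountError):
    """Invalid input data (files, annotations, coordinates)."""


class FormatError(DataError):
    """Unsupported or malformed file format."""


class AnnotationParseError(DataError):
    """Malformed annotation row; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class ValidationError(DataError):
    """A contract precondition was violated."""


class SamplingError(DataError):
    """Random sampling could not satisfy its constraints."""

    def __init__(self, message: str, achieved: int = 0):
        super().__init__(message)
        self.achieved = achieved


class GenerationError(PmfCountError):
    """Synthetic-data generation could not satisfy its constraints."""


class UndefinedMetricError(PmfCountError):
    """A ratio metric was requested with a zero denominator."""


class StageError(PmfCountError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
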
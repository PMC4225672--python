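"""Exception hierarchy for trnkit.

Every error raised by the library derives from :class:`TrnError` so callers
can catch the whole family at a pipeline boundary.
"""


class TrnError(Exception):
    """Base class for all trnkit errors."""


class EmptyNetworkError(TrnError):
    """Input yields a network with no nodes/edges where some are required."""


class ParseError(TrnError):
    """Malformed input line; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class ClassConflictError(TrnError):
    """The same regulator id appears with two different regulator classes."""


class WriteError(TrnError):
    """Network serialization failed."""


class DegenerateDistributionError(TrnError):
    """Degree distribution has no positive-degree support."""


class InsufficientDataError(TrnError):
    """Too few points to fit a tail model."""


class FitRangeError(TrnError):
    """Two tail fits being compared were not computed on the same points."""


class CutError(TrnError):
    """Requested more modules than clusterable nodes."""


class IncomparablePartitionsError(TrnError):
    """Two partitions share no nodes."""


class SpecError(TrnError):
    """Synthetic-network specification violates its invariants."""


class ConfigError(TrnError):
    """Pipeline configuration is missing or inconsistent."""


class StageError(TrnError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
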
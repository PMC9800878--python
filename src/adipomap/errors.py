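"""Exception types shared across the package."""


class AdipoMapError(Exception):
    """Base class for all package-specific errors."""


class EmptyOverlapError(AdipoMapError):
    """A query gene set shares no genes with a signature.

    Carries the realized overlap fraction (always 0.0) so callers can
    distinguish this from a below-threshold partial overlap.
    """

    def __init__(self, message: str, overlap: float = 0.0):
        super().__init__(message)
        self.overlap = overlap


class StageError(AdipoMapError):
    """A pipeline stage failed; names the stage for the run log."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
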
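"""Exception types shared across the pipeline."""


class PunctaQuantError(Exception):
    """Base class for all package errors."""


class MetadataError(PunctaQuantError):
    """Required physical metadata (voxel size, pixel size) is missing."""


class FormatError(PunctaQuantError):
    """Input file could not be parsed."""


class PlacementError(PunctaQuantError):
    """Synthetic objects could not be placed within the retry budget."""


class ParameterError(PunctaQuantError, ValueError):
    """Invalid model or scene parameter."""


class NormalizationError(PunctaQuantError):
    """FRAP trace cannot be normalized (non-positive reference)."""


class UndefinedMetricError(PunctaQuantError, ValueError):
    """Metric is undefined for the given inputs (e.g. K_p with LP <= 0)."""


class StageError(PunctaQuantError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, source: str, message: str):
        self.stage = stage
        self.source = source
        super().__init__(f"stage '{stage}' failed on '{source}': {message}")
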
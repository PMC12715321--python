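"""Exception hierarchy for the handwriting-analysis pipeline."""


class PenstrokeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PenstrokeError):
    """Invalid configuration value (unknown group, out-of-bounds artifact, ...)."""


class GenerationError(PenstrokeError):
    """A synthetic sheet could not be rendered (e.g. infeasible row area)."""


class SegmentationError(PenstrokeError):
    """Row segmentation found the wrong number of ink bands."""

    def __init__(self, message: str, found: int, expected: int):
        super().__init__(message)
        self.found = found
        self.expected = expected


class DatasetError(PenstrokeError):
    """Instance dataset could not be assembled (empty class, key mismatch, ...)."""


class MetricsError(PenstrokeError):
    """A micrographia metric is undefined for the given input."""
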
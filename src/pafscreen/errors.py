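"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`PafScreenError` so callers can
distinguish pipeline failures from programming errors.
"""


class PafScreenError(Exception):
    """Base class for all pipeline errors."""


class FormatError(PafScreenError, ValueError):
    """A file is structurally invalid (e.g. missing sampling-rate metadata)."""


class ParseError(PafScreenError, ValueError):
    """A file contains values that cannot be parsed."""


class InsufficientDataError(PafScreenError, ValueError):
    """Too little data to compute the requested quantity."""


class DetectionError(PafScreenError, RuntimeError):
    """R-peak detection found no usable beats."""


class DelineationError(PafScreenError, RuntimeError):
    """P-wave delineation failed on every beat."""


class ParameterError(PafScreenError, ValueError):
    """Generator or model parameters are out of their valid domain."""


class ConfigurationError(PafScreenError, ValueError):
    """An invalid configuration value."""


class TrainingError(PafScreenError, RuntimeError):
    """Ensemble training could not satisfy its contract (retry budget hit)."""


class FeatureExtractionError(PafScreenError, RuntimeError):
    """A stage of feature extraction failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
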
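"""Exception hierarchy. Every stage raises a subclass of :class:`ScintidetError`."""


class ScintidetError(Exception):
    """Base class for all toolkit errors."""


class DecodeError(ScintidetError):
    """An image file could not be read or has the wrong bit depth."""


class LabelParseError(ScintidetError):
    """A bounding-box label file is malformed."""


class ValidationError(ScintidetError):
    """An object violates its invariants (box geometry, manifest, config)."""


class GenerationError(ScintidetError):
    """The phantom generator could not satisfy a placement constraint."""


class DetectionRangeError(ScintidetError):
    """Body-range detection failed (e.g. all-zero image)."""


class CenteringError(ScintidetError):
    """A body crop does not fit the target canvas."""


class NormalizationError(ScintidetError):
    """Intensity normalization received a degenerate (zero-mean) input."""


class ExtractionError(ScintidetError):
    """Chest extraction preconditions not met (body too short)."""


class FusionError(ScintidetError):
    """AP/PA view fusion failed (size mismatch)."""


class FeatureError(ScintidetError):
    """A box is too degenerate to featurize."""


class TrainingError(ScintidetError):
    """Detector training could not proceed (e.g. no positive examples)."""


class ModelStateError(ScintidetError):
    """An operation was applied to a model in the wrong state."""


class SplitError(ScintidetError):
    """Cross-validation fold construction failed (stratum too small)."""


class PipelineError(ScintidetError):
    """A pipeline stage aborted; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
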
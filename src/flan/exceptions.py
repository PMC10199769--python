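"""Exception hierarchy.

All errors raised by this package derive from :class:`FlanError` so callers
can catch package-specific failures without masking programming errors.
"""


class FlanError(Exception):
    """Base class for all package errors."""


class SpecValidationError(FlanError, ValueError):
    """A FeatureSpec (or generator spec) is internally inconsistent."""


class InputShapeError(FlanError, ValueError):
    """Data does not conform to the FeatureSpec or model dimensions."""


class VocabularyError(FlanError, ValueError):
    """A sequence contains a token outside the declared vocabulary."""


class SequenceTooLongError(FlanError, ValueError):
    """A sequence exceeds the fixed encoding length; never silently truncated."""


class DegenerateLabelsError(FlanError, ValueError):
    """Training or a metric requires at least two classes."""


class UndefinedMetricError(FlanError, ValueError):
    """A metric is undefined for the given labels (e.g. single-class AUC)."""


class DivergenceError(FlanError, RuntimeError):
    """Training loss became non-finite. Carries the last stable parameters."""

    def __init__(self, message, last_stable_params=None, epoch=None):
        super().__init__(message)
        self.last_stable_params = last_stable_params
        self.epoch = epoch


class CheckpointError(FlanError, ValueError):
    """A checkpoint is missing, corrupt, or has an incompatible version."""
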
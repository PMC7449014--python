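"""Package-wide exceptions and warnings."""

from __future__ import annotations


class MorphoEETError(Exception):
    """Base class for all package errors."""


class ShapeViolationError(MorphoEETError, ValueError):
    """Projected dimensions do not describe a valid rod (e.g. L < D)."""


class DimensionUnderflowError(MorphoEETError, ValueError):
    """A corrected dimension would be non-positive."""


class InsufficientBinsError(MorphoEETError, ValueError):
    """Fewer than two length bins satisfy the minimum-count rule."""


class PipelineStageError(MorphoEETError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")


class SchemaError(MorphoEETError, ValueError):
    """A CSV input violated its declared schema."""


class ValidityRangeWarning(UserWarning):
    """Characteristic length outside the correlation's fitted range."""


class ExtrapolationWarning(UserWarning):
    """Prediction requested outside the fitted length range."""


class LinearRangeWarning(UserWarning):
    """Optical density above the linear region of the calibration curve."""


class DegenerateInputWarning(UserWarning):
    """Input is formally valid but statistically degenerate."""


class DenominatorZeroWarning(UserWarning):
    """MER denominator |delta(delta c)| is zero; the sigmoid limit 1 is returned."""
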
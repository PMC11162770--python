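"""Exceptions and warning categories shared across the package."""


class SsbdynError(Exception):
    """Base class for package errors."""


class InsufficientDataError(SsbdynError):
    """Too few samples to perform the requested computation."""


class FitFailureError(SsbdynError):
    """A nonlinear fit did not converge or the data violate its preconditions."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class EmptyOverlapError(SsbdynError):
    """Two curves share no distance support, so no area can be integrated."""


class SegmentationError(SsbdynError):
    """Image segmentation judged unreliable (e.g. saturated frame)."""


class AlreadyCorrectedError(SsbdynError):
    """Photobleaching correction applied twice."""


class ConfigError(SsbdynError):
    """Invalid pipeline run configuration."""


class ShortPlateauWarning(UserWarning):
    """Pre-onset plateau shorter than the stability requirement."""


class FloorWarning(UserWarning):
    """A rate was floored at zero during photobleaching correction."""


class SaturationWarning(UserWarning):
    """Coverage exceeded 1 and was capped."""


class RampMismatchWarning(UserWarning):
    """Hysteresis computed between phases with different ramp labels."""


class MonotonicityWarning(UserWarning):
    """Force series not monotone within a phase after median filtering."""


class NegativeCompactionWarning(UserWarning):
    """Initial length exceeds the reference: negative percent compaction."""


class IdentifiabilityWarning(UserWarning):
    """Fit parameters are weakly identifiable (near-degenerate rates, single
    concentration, etc.)."""


class ControlShapeWarning(UserWarning):
    """A photobleaching control trace deviates from single-exponential shape."""
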
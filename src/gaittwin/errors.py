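"""Exception types shared across the pipeline stages."""


class GaitTwinError(Exception):
    """Base class for all package errors."""


class ValidationError(GaitTwinError):
    """Invalid input values (non-positive measurements, malformed config...)."""


class NoStridesDetected(GaitTwinError):
    """Gait-event detection found no mid-swing peak above threshold."""


class InsufficientStrides(GaitTwinError):
    """Fewer strides than the minimum required by the requested computation."""


class EventSequenceError(GaitTwinError):
    """Left/right gait events do not interleave plausibly."""


class NoSolution(GaitTwinError):
    """No integer confusion matrix reproduces the requested metrics."""


class AmbiguousSolution(GaitTwinError):
    """More than one integer confusion matrix reproduces the requested metrics."""
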
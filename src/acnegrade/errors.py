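"""Exception types shared across the package."""


class AcnegradeError(Exception):
    """Base class for all package errors."""


class InvalidSizeError(AcnegradeError, ValueError):
    """Canvas or crop size below the supported minimum."""


class PlacementError(AcnegradeError, RuntimeError):
    """Lesion placement failed under the overlap rejection cap."""

    def __init__(self, category: str, requested: int, placed: int):
        self.category = category
        super().__init__(
            f"could not place lesion {placed + 1}/{requested} of category "
            f"{category!r} under the overlap rejection cap"
        )


class InvalidBoxError(AcnegradeError, ValueError):
    """Degenerate (zero-area) or malformed bounding box."""


class ConfigError(AcnegradeError, ValueError):
    """Invalid or non-exhaustive configuration."""


class InvalidGradeError(AcnegradeError, ValueError):
    """Severity grade outside 1..8."""


class InvalidMaskError(AcnegradeError, ValueError):
    """Interval weight mask with no admissible grade."""


class UndefinedStatisticError(AcnegradeError, ValueError):
    """Agreement statistic undefined for the given data (e.g. zero variance)."""


class LeakageError(AcnegradeError, ValueError):
    """Train/test subject overlap detected."""


class AlignmentError(AcnegradeError, ValueError):
    """Subject ids do not align between two inputs."""
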
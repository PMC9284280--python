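"""Exception hierarchy shared across the package."""


class MMDAError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(MMDAError):
    """Malformed or empty input data (e.g. a zero-size image)."""


class InvalidParameterError(MMDAError):
    """A parameter violates its contract (e.g. sigma <= 0)."""


class ShapeError(MMDAError):
    """Array shapes are inconsistent with each other."""


class InvalidLabelError(MMDAError):
    """A class index is outside [0, K)."""


class MissingLabelError(MMDAError):
    """Labelled data was required but labels are absent."""


class NumericError(MMDAError):
    """Non-finite values where finite ones are required."""


class InvalidDistributionError(MMDAError):
    """Probability rows are negative or do not sum to one."""


class DegenerateClassError(MMDAError):
    """A class received zero total soft mass during centroid construction."""

    def __init__(self, class_index: int, message: str | None = None):
        self.class_index = class_index
        super().__init__(message or f"class {class_index} has zero total soft mass")


class UndefinedDistanceError(MMDAError):
    """Cosine distance is undefined for a zero-norm vector."""


class UndefinedMetricError(MMDAError):
    """A metric's denominator is zero or the truth vector is single-class."""


class IncompatibilityError(MMDAError):
    """Source bundles disagree on feature dimension d or class count K."""


class ConfigError(MMDAError):
    """Configuration file is malformed or contains unknown keys."""
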
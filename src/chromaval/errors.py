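"""Exception hierarchy shared by all chromaval modules."""


class ChromavalError(Exception):
    """Base class for all chromaval-specific errors."""


class InvalidPeakError(ChromavalError):
    """Peak descriptors violate a physical constraint (non-positive width, t_R < t_0, ...)."""


class StatisticUndefinedError(ChromavalError):
    """Too few observations, or a degenerate value, for the requested statistic."""


class NoDataError(ChromavalError):
    """An operation received an empty collection."""


class FitUndefinedError(ChromavalError):
    """A regression cannot be computed (too few levels, zero variance in x, ...)."""


class TestUndefinedError(ChromavalError):
    """A hypothesis test cannot be computed (single replicate, zero variance, ...)."""


class WeightUndefinedError(ChromavalError):
    """A weighting scheme divides by a zero concentration or response."""


class LimitsUndefinedError(ChromavalError):
    """Detection limits cannot be derived (zero slope)."""


class InputMismatchError(ChromavalError):
    """Two inputs that must describe the same data disagree in shape or content."""


class InvalidInputError(ChromavalError):
    """A scalar argument is outside its valid domain."""


class LogUndefinedError(ChromavalError):
    """A logarithm was requested of a non-positive value."""


class NormalizationError(ChromavalError):
    """A series expected to be normalized to 100% at time zero is not."""


class InvalidSpecError(ChromavalError):
    """A simulation specification violates its constraints."""


class MeasurementError(ChromavalError):
    """A synthetic trace could not be measured (no peak, thresholds not crossed)."""


class ConfigError(ChromavalError):
    """A pipeline configuration file is missing or malformed."""
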
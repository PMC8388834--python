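"""Exception hierarchy.

Every error raised by fluogrowth derives from :class:`FluoGrowthError`, so
callers (and the CLI) can catch one type at the pipeline boundary.
"""


class FluoGrowthError(Exception):
    """Base class for all fluogrowth errors."""


class ParseError(FluoGrowthError):
    """Malformed input file (bad well id, non-monotone time column, ...)."""


class MergeError(FluoGrowthError):
    """Channel fragments cannot be merged (mismatched wells or time grids)."""


class LayoutError(FluoGrowthError):
    """Invalid plate layout (well outside plate, duplicate reporter, ...)."""


class ConfigurationError(FluoGrowthError):
    """A requested operation is inconsistent with the layout or config."""


class InsufficientDataError(FluoGrowthError):
    """Too few finite observations for the requested statistic."""


class UndefinedCorrelationError(FluoGrowthError):
    """Correlation undefined because an argument has zero variance."""


class ConvergenceError(FluoGrowthError):
    """Iterative fit did not converge within the iteration budget."""

    def __init__(self, message: str, iterations: int | None = None):
        super().__init__(message)
        self.iterations = iterations


class NormalizationError(FluoGrowthError):
    """Fitness normalization impossible (non-positive monoculture mean)."""


class ThresholdError(FluoGrowthError):
    """No threshold exists (constant image)."""


class BackgroundError(FluoGrowthError):
    """No background pixels available for background estimation."""


class IntegrationError(FluoGrowthError):
    """ODE integration produced a non-finite state."""


class PlacementError(FluoGrowthError):
    """Could not place synthetic cells without overlap within the retry budget."""
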
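"""Exception hierarchy for polartrack.

All errors derive from :class:`PolartrackError` (a ``ValueError``) so callers
can catch everything from this package with one clause while still getting
sensible behaviour from generic ``except ValueError`` code.
"""


class PolartrackError(ValueError):
    """Base class for all polartrack errors."""


class ParameterError(PolartrackError):
    """An operation parameter is out of its valid range."""


class GeometryError(PolartrackError):
    """An ROI or path does not intersect the image as required."""


class InputError(PolartrackError):
    """Malformed or inconsistent input data."""


class NormalizationError(PolartrackError):
    """A trace cannot be normalized (e.g. nonpositive first value)."""


class StatisticsError(PolartrackError):
    """Too few observations, or a degenerate sample, for the requested statistic."""


class AnalysisError(PolartrackError):
    """A downstream analysis precondition is violated (e.g. zero-variance bait)."""
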
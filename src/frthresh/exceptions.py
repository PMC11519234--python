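"""Exception hierarchy.

All package errors derive from :class:`FRThreshError` so callers can catch
one base class; the leaves distinguish input-format problems from
physiologically or numerically degenerate situations.
"""


class FRThreshError(Exception):
    """Base class for all frthresh errors."""


class InputFormatError(FRThreshError, ValueError):
    """A file or table is structurally invalid (e.g. a required column is missing)."""


class StageValidationError(FRThreshError, ValueError):
    """Stage data violate an invariant (negative power, non-monotone power, ...)."""


class InsufficientDataError(FRThreshError, ValueError):
    """Too few stages / points for the requested computation."""


class DomainError(FRThreshError, ValueError):
    """A numeric argument is outside its physical domain (e.g. peak <= 0)."""


class DegenerateFitError(FRThreshError, ValueError):
    """A regression cannot be fitted (identical predictor values, n < 2, ...)."""


class NoIntersectionError(FRThreshError, ValueError):
    """Two regression lines are parallel within tolerance."""
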
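"""Exception hierarchy for rhcmr.

All domain errors derive from :class:`RhcmrError` so callers can catch one
base class at pipeline boundaries.
"""


class RhcmrError(Exception):
    """Base class for all rhcmr domain errors."""


class InvalidContourError(RhcmrError):
    """A polygon has fewer than 3 vertices, is self-intersecting, or has zero area."""


class MissingStructureError(RhcmrError):
    """No contour of the requested structure exists at the requested phase."""


class InsufficientPhasesError(RhcmrError):
    """Fewer than two phases carry endocardial contours; ED/ES cannot be selected."""


class InconsistentContourError(RhcmrError):
    """An epicardial contour encloses less area than its endocardial partner."""


class InvalidBsaError(RhcmrError):
    """Body surface area is non-positive."""


class InvalidAnthropometryError(RhcmrError):
    """Height or weight is non-positive."""


class InvalidLandmarksError(RhcmrError):
    """Degenerate 4-chamber landmarks (e.g. annulus coincides with apex)."""


class EmptyRoiError(RhcmrError):
    """A velocity-map region-of-interest mask contains no pixels."""


class NotPositiveDefiniteError(RhcmrError):
    """A requested copula correlation structure is infeasible."""


class ValidationError(RhcmrError):
    """An input file violates its schema; message names file, row and field."""
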
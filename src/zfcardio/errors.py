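"""Exception hierarchy for the phenotyping pipeline.

Every failure mode a pipeline stage can hit maps to one exception class so
callers (and the cohort runner) can record *why* an individual was dropped.
"""


class ZfCardioError(Exception):
    """Base class for all pipeline errors."""


class FormatError(ZfCardioError):
    """Input file violates the expected format (non-grayscale, ragged pages...)."""


class GeometryError(ZfCardioError):
    """A simulated or measured structure violates geometric constraints."""


class NoObjectError(ZfCardioError):
    """Segmentation found no foreground object."""


class DegenerateRegionError(ZfCardioError):
    """Region too small or collinear for an ellipse fit."""


class NoBeatError(ZfCardioError):
    """Beat detection failed: flat series or fewer than three complete beats."""


class InsufficientTrackError(ZfCardioError):
    """A track is shorter than the scoring window."""


class InsufficientCellsError(ZfCardioError):
    """Fewer trackable cells than the protocol requires."""


class SeedMissError(ZfCardioError):
    """Component-selection seed voxel lies in the background."""


class SampleTooSmallError(ZfCardioError):
    """Sample below the minimum n for the requested statistic."""


class InconsistentReportError(ZfCardioError):
    """Derived report fields violate an internal invariant (e.g. ESV > EDV)."""


class CohortError(ZfCardioError):
    """Cohort-level failure (group too small, all individuals failed...)."""
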
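"""Exception hierarchy for the avishift pipeline.

Stage code raises these; the batch orchestrator catches :class:`SpeciesError`
subclasses per species and logs them without aborting the run, while
:class:`ConfigurationError` and :class:`AlignmentError` abort immediately.
"""


class AvishiftError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AvishiftError):
    """Invalid run/world configuration (bad grid dims, non-positive cell size...)."""


class AlignmentError(AvishiftError):
    """Rasters do not share shape, origin or cell size."""


class UnsupportedCRSError(AvishiftError):
    """Raster file is not in a geographic (lon/lat) coordinate system."""


class EmptyInputError(AvishiftError):
    """An input table or grid is empty where data is required."""


class SpeciesError(AvishiftError):
    """Base for per-species failures that the batch runner logs and skips."""

    def __init__(self, message: str, species_id: str | None = None):
        super().__init__(message)
        self.species_id = species_id


class DegenerateSpeciesError(SpeciesError):
    """All sampling weights zero, or no viable occurrence signal."""


class InsufficientDataError(SpeciesError):
    """Too few points/scores for the requested computation."""


class NoRegionError(SpeciesError):
    """Species presences fall outside every region of the partition."""


class FitError(SpeciesError):
    """Model fitting failed (e.g. constant feature column)."""


class ProjectionError(SpeciesError):
    """A climate band required by a fitted model is missing."""


class DegenerateModelError(SpeciesError):
    """Variable pruning removed every variable."""


class UndefinedChangeError(SpeciesError):
    """Percentage range change undefined because the current area is zero."""


class NoCenterError(SpeciesError):
    """Median centre requested for an empty range."""


class KeyingError(AvishiftError):
    """Records and metadata tables do not key consistently."""


class UndefinedCoverageError(AvishiftError):
    """Coverage statistic requested for an empty priority set."""
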
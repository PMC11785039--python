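"""Exception hierarchy. Every contract violation raises a distinct, named error."""


class ChemoshiftError(Exception):
    """Base class for all package errors."""


class UnassignedSampleError(ChemoshiftError):
    """A sample in the expression matrix has no row in the sample sheet."""


class UnknownSampleError(ChemoshiftError):
    """The sample sheet names a sample absent from the expression matrix."""


class DuplicateGeneError(ChemoshiftError):
    """A gene (or probe) identifier occurs more than once in a matrix."""


class DuplicateSampleError(ChemoshiftError):
    """A sample identifier occurs more than once."""


class NonNumericValueError(ChemoshiftError):
    """An expression cell is missing or not parseable as a finite number."""


class FactorLevelError(ChemoshiftError):
    """A design factor does not have exactly two levels."""


class MalformedGMTError(ChemoshiftError):
    """A GMT line has fewer than three tab-separated fields."""


class DuplicateSetNameError(ChemoshiftError):
    """Two gene sets in one collection share a name."""


class EmptyCellError(ChemoshiftError):
    """A treatment x phenotype design cell contains no samples."""


class NonPositiveValueError(ChemoshiftError):
    """log2 requested on a non-positive intensity."""


class EmptyResultError(ChemoshiftError):
    """An operation produced no output rows (e.g. no probe survived mapping)."""


class EmptyUniverseError(ChemoshiftError):
    """Enrichment requested against an empty gene universe."""


class SetNotRepresentedError(ChemoshiftError):
    """A gene set has no members inside the enrichment universe."""


class FractionError(ChemoshiftError):
    """Tail fraction outside the open interval (0, 0.5)."""


class MeasurementError(ChemoshiftError):
    """Invalid caliper measurement (negative dimension, too few timepoints...)."""


class ConfigError(ChemoshiftError):
    """Invalid simulation or pipeline configuration."""
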
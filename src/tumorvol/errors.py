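"""Exception hierarchy shared across the package."""


class TumorvolError(Exception):
    """Base class for all package-specific errors."""


class MaskError(TumorvolError):
    """Invalid segmentation mask (multi-label, wrong dimensionality, bad spacing...)."""


class EmptyMaskError(MaskError):
    """Mask contains no foreground voxels where at least one is required."""


class MultiComponentError(MaskError):
    """Mask contains more than one 26-connected foreground component."""


class DegenerateGeometryError(TumorvolError):
    """Point set has insufficient affine rank for the requested computation."""


class ConvergenceError(TumorvolError):
    """Iterative solver failed to reach its tolerance within the iteration cap."""


class StatisticsError(TumorvolError):
    """Degenerate input to a statistical routine (constant vector, too few cases...)."""


class CohortError(TumorvolError):
    """Cohort generation could not satisfy its constraints."""


class ConfigError(TumorvolError):
    """Pipeline configuration violates its schema."""


class NoValidCasesError(TumorvolError):
    """Pipeline received no analyzable cases."""
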
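"""Exception hierarchy shared across the pipelines."""


class ReceptorQuantError(Exception):
    """Base class for all package-specific errors."""


class MalformedFileError(ReceptorQuantError):
    """An input file does not match the declared layout (e.g. odd page count)."""


class ConfigurationError(ReceptorQuantError):
    """Required metadata or configuration is missing or inconsistent."""


class DegenerateHistogramError(ReceptorQuantError):
    """A plane has fewer than two distinct intensity values; no threshold exists."""


class SegmentationError(ReceptorQuantError):
    """Segmentation produced an empty foreground on an analyzed slice."""


class ContourError(ReceptorQuantError):
    """A mask violates the single-component / no-holes contract for tracing."""


class DegenerateGeometryError(ReceptorQuantError):
    """Morphological erosion emptied the cell mask (cell thinner than the band)."""


class EpochError(ReceptorQuantError):
    """A spike experiment lacks the epochs required for a metric."""


class ZeroBaselineError(EpochError):
    """Baseline firing rate is zero; the cell fails the steady-firing inclusion rule."""


class FitError(ReceptorQuantError):
    """Nonlinear least squares failed to converge."""
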
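"""Exception hierarchy for the perfusion/stratification pipeline.

Every domain failure derives from :class:`PerfstratError` so callers (and the
pipeline driver, which converts failures into CONSORT-style exclusion records)
can catch one base class.
"""


class PerfstratError(Exception):
    """Base class for all package-domain errors."""


class ParameterError(PerfstratError, ValueError):
    """A model or algorithm parameter is outside its valid domain."""


class ConfigurationError(PerfstratError, ValueError):
    """A phantom/cohort/pipeline configuration is inconsistent."""


class ConversionError(PerfstratError):
    """Signal-to-concentration conversion failed (e.g. nonpositive sample)."""


class DetectionError(PerfstratError):
    """No acceptable arterial input function candidate was found."""


class CorrectionError(PerfstratError):
    """Leakage correction could not be performed (degenerate reference)."""


class NormalizationError(PerfstratError):
    """Relative-map normalization failed (empty or invalid reference region)."""


class DelineationError(PerfstratError):
    """Habitat delineation failed (too few voxels, grid mismatch)."""


class MarkerError(PerfstratError):
    """Vascular marker could not be computed (empty habitat)."""


class ImputationError(PerfstratError):
    """Mean imputation failed (no observed values)."""


class FitError(PerfstratError):
    """A statistical model fit failed or did not converge."""


class AnalysisError(PerfstratError):
    """A survival/group analysis received an unusable subset."""
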
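"""Typed exceptions used across the pipeline stages."""


class GlymphalpsError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(GlymphalpsError):
    """Invalid parameter or specification (caught before any computation)."""


class FitError(GlymphalpsError):
    """Tensor estimation failed (e.g. rank-deficient gradient design)."""


class ROIError(GlymphalpsError):
    """ROI selection produced an empty or invalid region."""


class ALPSError(GlymphalpsError):
    """ALPS-index computation received degenerate inputs."""


class RegressionError(GlymphalpsError):
    """Singular or under-determined regression design."""


class IOValidationError(GlymphalpsError):
    """A file failed schema or invariant validation on read/write."""
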
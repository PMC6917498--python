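"""Exception hierarchy shared across the pipeline stages."""


class GeoconnError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GeoconnError, ValueError):
    """An invalid or internally inconsistent configuration."""


class ValidationError(GeoconnError, ValueError):
    """Input data violates a documented precondition (range, shape, finiteness)."""


class DegenerateDataError(GeoconnError, ValueError):
    """Data are degenerate for the requested statistic (zero variance, empty margin)."""


class DesignError(GeoconnError, ValueError):
    """A model design matrix is rank deficient or otherwise unusable."""


class EstimabilityError(GeoconnError, ValueError):
    """Too few observations to estimate the requested model."""
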
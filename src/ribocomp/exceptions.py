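"""Exception hierarchy for ribocomp."""


class RibocompError(Exception):
    """Base class for all ribocomp errors."""


class ValidationError(RibocompError, ValueError):
    """Raised when model inputs violate their domain (negative counts,
    non-finite values, non-PSD moment matrices, empty populations)."""


class CalibrationError(RibocompError, ValueError):
    """Raised when a requested Pearson correlation is unattainable for the
    configured marginal distributions under the Gaussian copula."""


class UndefinedCorrelationError(RibocompError, ValueError):
    """Raised when a correlation is requested but one of the variables has
    zero variance."""


class UnitEstimationError(RibocompError, RuntimeError):
    """Raised when the single-transcript unit intensity cannot be estimated
    (no cells above the false-positive threshold)."""
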
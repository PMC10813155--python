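"""Exception hierarchy."""


class SwayHMMError(Exception):
    """Base class for all package errors."""


class ModelValidityError(SwayHMMError):
    """Model parameters violate an invariant (non-stochastic row,
    non-positive-definite covariance, unsupported chain order, ...)."""


class DimensionMismatchError(SwayHMMError):
    """Observation dimension incompatible with the model."""


class SequenceError(SwayHMMError):
    """Invalid observation sequence (empty, NaN, ...)."""


class StarvedStateError(SwayHMMError):
    """A state or mixture component received (near-)zero posterior mass."""


class CopFileError(SwayHMMError):
    """Base class for COP file / manifest format errors."""


class MissingColumnError(CopFileError):
    pass


class NonMonotoneTimeError(CopFileError):
    pass


class NaNValueError(CopFileError):
    pass


class SamplingRateError(CopFileError):
    pass


class ManifestError(CopFileError):
    pass
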
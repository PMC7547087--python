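"""Exception types shared across the pipeline."""


class ErvdynError(Exception):
    """Base class for all package errors."""


class ParameterError(ErvdynError, ValueError):
    """A function argument violates its contract."""


class DataError(ErvdynError, ValueError):
    """Input data violates a stated precondition (e.g. negative coverage)."""


class ConfigurationError(ErvdynError, ValueError):
    """A configuration mapping is incomplete or inconsistent."""


class PlacementError(ErvdynError, RuntimeError):
    """An interval could not be placed after the allowed number of attempts."""


class NormalizationError(ErvdynError, ValueError):
    """A coverage track cannot be normalized (e.g. zero total signal)."""


class ContractError(ErvdynError, ValueError):
    """An object is used in a context its normalization tag forbids."""


class DegenerateTestError(ErvdynError, ValueError):
    """A statistical test is undefined on the given data (zero variance)."""


class AnnotationError(ErvdynError, ValueError):
    """Annotation does not satisfy its contract (e.g. segmentation gaps)."""
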
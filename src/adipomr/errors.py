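"""Exception hierarchy.

Everything raised deliberately by this package derives from :class:`AdipoMRError`
so callers can catch pipeline failures without swallowing programming errors.
"""


class AdipoMRError(Exception):
    """Base class for all errors raised by adipomr."""


class SchemaError(AdipoMRError):
    """A summary-statistics table does not match its declared schema."""


class EmptyInputError(AdipoMRError):
    """An operation received no usable rows/records."""


class MissingSNPError(AdipoMRError, KeyError):
    """A SNP id required by an operation is absent from its input."""


class HarmonisationError(AdipoMRError):
    """Exposure/outcome records could not be placed on a common allele orientation."""


class DegenerateInstrumentError(AdipoMRError):
    """An instrument cannot support estimation (e.g. zero SNP-exposure effect)."""


class ConditioningError(AdipoMRError):
    """A covariance matrix is numerically singular beyond the permitted ridge."""


class DomainError(AdipoMRError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class ConfigError(AdipoMRError):
    """A configuration object is internally inconsistent."""
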
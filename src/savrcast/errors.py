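"""Exception hierarchy shared across the package."""


class SavrcastError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(SavrcastError):
    """A required column or field is missing from an input table."""


class ValidationError(SavrcastError):
    """A record or panel violates a structural invariant."""


class CapabilityError(SavrcastError):
    """The requested computation needs data the input does not carry
    (e.g. a sex split on an all-sex panel, or a longevity index without
    a >=75 band)."""


class UndefinedIndexError(SavrcastError):
    """An index is undefined for this record (zero denominator)."""


class InsufficientDataError(SavrcastError):
    """Too few observations for the requested statistical procedure."""


class GrowthDomainError(SavrcastError):
    """Inputs outside the domain of the growth model (non-positive
    population, non-positive duration, rate <= -100%)."""
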
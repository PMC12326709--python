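"""Exception hierarchy for castscan.

Every user-facing failure mode raises a subclass of :class:`CastscanError`
so callers can catch the package's errors without catching unrelated ones.
"""


class CastscanError(Exception):
    """Base class for all castscan errors."""


class InvalidArgumentError(CastscanError, ValueError):
    """An argument violates a documented precondition."""


class EmptyInputError(CastscanError, ValueError):
    """An operation that needs at least one record received none."""


class AmbiguousMatchError(CastscanError):
    """Two distinct transposon-end identities matched a read equally well."""


class MultimapError(CastscanError):
    """A genomic flank placed equally well at more than one locus."""


class TooShortError(CastscanError):
    """A genomic flank is shorter than the minimum mappable length."""


class UnmappedFlankError(CastscanError):
    """A genomic flank found no placement within the edit bound."""


class InconsistentJunctionsError(CastscanError):
    """Paired junction coordinates imply a physically impossible duplication."""


class ConfigError(CastscanError, ValueError):
    """A pipeline configuration is invalid or incomplete."""
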
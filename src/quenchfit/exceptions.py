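"""Exception hierarchy.

Everything derives from :class:`QuenchFitError` so callers can catch the
package's failures with a single ``except`` clause; the subclasses mirror
the distinct failure modes of the pipeline (bad files, bad values, fits
that cannot proceed, fits that contradict the quenching model).
"""


class QuenchFitError(Exception):
    """Base class for all errors raised by quenchfit."""


class FormatError(QuenchFitError):
    """A file does not conform to the documented CSV layout."""


class ValidationError(QuenchFitError):
    """A domain object violates one of its invariants."""


class DomainError(QuenchFitError):
    """An argument is outside the mathematical domain of an operation."""


class InsufficientDataError(QuenchFitError):
    """Fewer usable points than the minimum a fit requires."""


class FitInvalidError(QuenchFitError):
    """The fitted line contradicts the quenching model (non-positive
    slope or intercept on the transformed coordinates)."""


class CapabilityError(QuenchFitError):
    """The requested operation needs data the object does not carry
    (e.g. full emission scans on a scalar-only titration series)."""
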
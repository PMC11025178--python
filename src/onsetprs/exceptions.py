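"""Exception hierarchy for onsetprs.

All package errors derive from :class:`OnsetPRSError` so callers can catch
broadly; the subclasses mirror the failure modes of the individual stages.
"""


class OnsetPRSError(Exception):
    """Base class for all onsetprs errors."""


class ConfigurationError(OnsetPRSError):
    """A simulation or pipeline configuration field is invalid."""


class ValidationError(OnsetPRSError):
    """An input table or value violates its documented contract."""


class EmptyInputError(ValidationError):
    """An operation received an empty matrix or table."""


class DegenerateSimulationError(OnsetPRSError):
    """The simulation setup cannot produce any events (e.g. all-zero hazard)."""


class InsufficientDataError(OnsetPRSError):
    """Too few complete observations to compute the requested quantity."""


class InsufficientVariationError(InsufficientDataError):
    """A vector is constant where variation is required (e.g. LD r2)."""


class NoEventsError(OnsetPRSError):
    """A survival fit was requested on a cohort with zero events."""


class ConvergenceError(OnsetPRSError):
    """An iterative fit failed to converge; carries the iteration trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace or []


class SeparationError(OnsetPRSError):
    """Perfect separation (or no information) in a logistic fit."""


class ZeroIncidenceError(OnsetPRSError):
    """A non-case needs a sampling weight at an age with zero incidence."""


class MissingVariantError(OnsetPRSError):
    """Too many PRS model variants are absent from the genotype matrix."""


class InsufficientInstrumentsError(OnsetPRSError):
    """An MR estimator was given fewer instruments than it requires."""
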
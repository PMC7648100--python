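"""Exception hierarchy for the MR pipeline.

Every error raised by the library derives from :class:`IbdMrError` so that
pipeline code can trap analysis failures per exposure-outcome pair without
masking programming errors.
"""


class IbdMrError(Exception):
    """Base class for all library errors."""


class SummaryFormatError(IbdMrError):
    """A summary-statistic file is malformed (missing column, bad header)."""


class EmptyInputError(IbdMrError):
    """A summary-statistic file contained no valid rows."""


class EmptyInstrumentError(IbdMrError):
    """Harmonization produced no usable SNPs (empty rsid intersection)."""


class ConfigurationError(IbdMrError):
    """A required setting is missing or inconsistent (e.g. no trait SD)."""


class ShapeError(IbdMrError):
    """A matrix dimension does not match its companion SNP list."""


class DegenerateInstrumentError(IbdMrError):
    """A Wald ratio is undefined because an exposure beta is exactly zero."""


class InsufficientInstrumentsError(IbdMrError):
    """An estimator's minimum SNP count is not met.

    Pipeline code records NA for the method instead of aborting the study.
    """


class ConvergenceError(IbdMrError):
    """Numerical optimization failed to converge within the iteration cap."""
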
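"""Exception hierarchy for ivmr.

All package errors derive from :class:`IvmrError` so callers can catch one
base class at the pipeline boundary.
"""


class IvmrError(Exception):
    """Base class for all ivmr errors."""


class ConfigurationError(IvmrError):
    """A column mapping, config file or option is wrong or incomplete."""


class FormatError(IvmrError):
    """An input file violates its declared tabular format."""


class EmptyInputError(IvmrError):
    """An input file contains no data rows."""


class ValidationError(IvmrError):
    """Input records violate a semantic invariant (duplicates, bad scales...)."""


class EstimationError(IvmrError):
    """An estimator cannot be computed on the given instruments."""


class NoInstrumentsError(IvmrError):
    """Instrument selection left zero variants; analysis cannot proceed."""
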
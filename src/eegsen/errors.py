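"""Exception hierarchy for the eegsen pipeline.

Every stage raises a subclass of :class:`EegsenError` so callers can catch
pipeline failures without masking programming errors.
"""


class EegsenError(Exception):
    """Base class for all eegsen errors."""


class FormatError(EegsenError):
    """Malformed input file (ragged rows, non-numeric cells, empty input)."""


class ParseError(FormatError):
    """A specific cell could not be parsed; message names row and column."""


class TruncationError(FormatError):
    """Binary file size is not a whole number of frames."""


class InsufficientHistoryError(EegsenError):
    """The requested preictal window starts before the recording does."""


class FilterDesignError(EegsenError):
    """A filter cannot be designed for the requested band and rate."""


class InsufficientDataError(EegsenError):
    """Too few usable points for a regression fit."""


class IncompleteCohortError(EegsenError):
    """A patient row is missing one or more band summaries."""


class InfeasibleDriftError(EegsenError):
    """A programmed entropy drift leaves the achievable SEN range."""
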
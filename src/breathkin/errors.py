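"""Exception hierarchy.

Every error the library raises derives from :class:`BreathkinError`, so callers
(and the CLI) can distinguish invalid input (exit code 1) from a failed
pipeline stage (exit code 2).
"""


class BreathkinError(Exception):
    """Base class for all breathkin errors."""


class InvalidParameterError(BreathkinError, ValueError):
    """A model or configuration parameter is out of its admissible range."""


class InvalidInputError(BreathkinError, ValueError):
    """Data passed to an operation violates its preconditions."""


class InsufficientDataError(BreathkinError):
    """Too few observations to compute the requested quantity."""


class IncompleteWindowError(BreathkinError):
    """Observations do not span (or flank) the requested integration window."""


class ParseError(BreathkinError):
    """A data file violates the expected schema; message names the row/column."""


class DegenerateDataError(BreathkinError):
    """A data matrix is rank deficient or constant; message names the column."""


class StageFailureError(BreathkinError):
    """A pipeline stage failed; message names the stage and the cause."""
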
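"""Exception hierarchy.

Validation problems (bad inputs, malformed tables) and numerical failures
(non-convergence, existence-condition violations) are kept distinct so the
command line can map them to different exit codes.
"""


class PeakDriftError(Exception):
    """Base class for all package errors."""


class ValidationError(PeakDriftError):
    """Invalid input data or configuration. CLI exit code 2."""

    exit_code = 2


class NumericalError(PeakDriftError):
    """A numerical procedure failed or is undefined. CLI exit code 3."""

    exit_code = 3


class TraceExistenceError(NumericalError):
    """The implicit-function existence condition for the trace is violated."""
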
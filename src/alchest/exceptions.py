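"""Exception hierarchy.

Everything raised deliberately by :mod:`alchest` derives from
:class:`AlchestError` so callers can catch the library's own failures
without swallowing programming errors.  Classes additionally derive from
the closest builtin (``ValueError``/``RuntimeError``) so that generic
handling keeps working.
"""


class AlchestError(Exception):
    """Base class for all alchest errors."""


class UnitError(AlchestError, ValueError):
    """Unknown or unsupported energy unit tag."""


class MetadataError(AlchestError, ValueError):
    """Missing or invalid table metadata (e.g. no temperature)."""


class FormatError(AlchestError, ValueError):
    """Malformed input file (XVG or alchest CSV)."""


class IncompatibleTablesError(AlchestError, ValueError):
    """Tables cannot be combined (unit / temperature / column mismatch)."""


class ValidationError(AlchestError, ValueError):
    """Data violates a structural invariant of the standard tables."""


class EstimationError(AlchestError, RuntimeError):
    """A free-energy estimator could not produce a result from the data."""


class ConvergenceError(EstimationError):
    """Iterative solver failed to converge.

    Attributes
    ----------
    last_iterate : object
        State of the solver when iteration stopped (e.g. the free-energy
        vector), useful for restarts and debugging.
    """

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class PolicyError(AlchestError, ValueError):
    """A decorrelation series policy cannot be applied to this table."""


class WorkflowError(AlchestError, RuntimeError):
    """End-to-end workflow failed (no inputs, or all estimators failed)."""
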
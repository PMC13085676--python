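"""Exception hierarchy.

Zero-probability conditioning events and zero-case denominators raise
explicit errors rather than propagating NaN: a silent NaN usually means a
mis-specified scenario, and the error names the offending cell.
"""


class PrevfracError(Exception):
    """Base class for all package errors."""


class SpecValidationError(PrevfracError):
    """A population specification violates an invariant (mass sums,
    negative probabilities, missing (stratum, arm) cells)."""


class UndefinedConditionalError(PrevfracError):
    """Conditioning on an event with probability zero."""


class UndefinedMeasureError(PrevfracError):
    """A measure's denominator (a case probability) is zero."""


class NotIdentifiableError(PrevfracError):
    """The requested estimand is not identified from the supplied data
    under the declared assumptions."""


class PositivityError(PrevfracError):
    """An (arm, stratum) cell required by the estimator has no observations."""


class RecordError(PrevfracError):
    """Malformed individual-level records (bad codes, consistency violation,
    empty table)."""
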
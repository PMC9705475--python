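"""Small shared helpers and the package error hierarchy."""

from __future__ import annotations

import decimal


class MammotriageError(Exception):
    """Base class for all package errors."""


class SchemaError(MammotriageError):
    """Cohort file violates the column/identifier contract."""


class CohortValidationError(MammotriageError):
    """One or more examinations violate a cohort invariant."""


class SpecError(MammotriageError):
    """A scenario specification is malformed (e.g. bands do not partition (0, 10])."""


class CalibrationError(MammotriageError):
    """Requested marginal targets are jointly infeasible for the generative model."""


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, the convention used for all reported rates.

    Python's builtin ``round`` uses banker's rounding (62.5 -> 62); reported
    screening rates and volume reductions use half-up (62.5 -> 63).
    """
    q = decimal.Decimal(10) ** -ndigits
    d = decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP)
    return float(d)
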
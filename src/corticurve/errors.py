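"""Typed errors and exclusion signals.

Participant exclusions during preprocessing are signalled with dedicated
exception types carrying a human-readable reason, so that exclusion
counts stay auditable instead of silently dropping data.
"""

from __future__ import annotations

__all__ = [
    "CorticurveError",
    "ParameterDomainError",
    "FlatCurveError",
    "ExclusionError",
    "NoBaselineError",
    "UnclassifiableResponderError",
    "ConvergenceError",
    "ValidationError",
    "DegenerateTestError",
]


class CorticurveError(Exception):
    """Base class for all package errors."""


class ParameterDomainError(CorticurveError, ValueError):
    """A parameter is outside its mathematical domain."""


class FlatCurveError(CorticurveError, ValueError):
    """A constant curve was given where a peak is required."""


class ExclusionError(CorticurveError):
    """A participant/procedure must be excluded; ``reason`` says why."""

    def __init__(self, reason: str, participant_id=None):
        self.reason = reason
        self.participant_id = participant_id
        msg = reason if participant_id is None else f"{participant_id}: {reason}"
        super().__init__(msg)


class NoBaselineError(ExclusionError):
    """No sample available to form a corrected t = 0 baseline."""


class UnclassifiableResponderError(ExclusionError):
    """No sample in the responder window; responder status undefined."""


class ConvergenceError(CorticurveError, RuntimeError):
    """An iterative fit failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


class ValidationError(CorticurveError, ValueError):
    """Input data failed validation; message lists offending rows."""


class DegenerateTestError(CorticurveError, ValueError):
    """A statistical test is undefined on the given input (e.g. zero variance)."""
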
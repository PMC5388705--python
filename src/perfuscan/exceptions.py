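"""Package-wide exception hierarchy.

Exit-code mapping used by the CLI: :class:`InputError` -> 2,
:class:`ComputationError` (and subclasses) -> 1.
"""

from __future__ import annotations


class PerfuscanError(Exception):
    """Base class for all package errors."""


class InputError(PerfuscanError):
    """Invalid user input: malformed file, bad schema, out-of-domain value."""


class DomainError(InputError):
    """A numeric argument violates a physical precondition (e.g. rho <= 0)."""


class ComputationError(PerfuscanError):
    """A computation failed (fit divergence, undefined statistic, ...)."""


class FitError(ComputationError):
    """Nonlinear or linear least squares failed.

    Carries the best candidate result found so far (may be ``None``) so
    callers can inspect how far the optimiser got.
    """

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


class ExtrapolationWarning(UserWarning):
    """Emitted when an empirical temperature model is evaluated outside
    the [0, 40] degC band the underlying measurements plausibly cover."""
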
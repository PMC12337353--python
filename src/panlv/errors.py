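"""Exception types shared across the package."""


class PanlvError(Exception):
    """Base class for package-specific errors."""


class GlobalExtinctionError(PanlvError):
    """Raised when one whole side of the community (bacteria or phage) is empty.

    Carries which side collapsed and the model time at which it happened so
    that callers can log the event instead of treating it as a failure.
    """

    def __init__(self, side: str, t: float | None = None):
        self.side = side
        self.t = t
        msg = f"global extinction of the {side} population"
        if t is not None:
            msg += f" at t={t:g}"
        super().__init__(msg)


class InsufficientDataError(PanlvError, ValueError):
    """Too few samples / snapshots / peaks to compute the requested statistic."""


class DegenerateFitError(PanlvError, ValueError):
    """Input data admits no meaningful two-parameter fit (e.g. all equal)."""


class BracketError(PanlvError, ValueError):
    """Bisection bracket endpoints classify to the same side of the boundary."""
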
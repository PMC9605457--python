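"""Exception hierarchy shared across the package."""


class PulsevarError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(PulsevarError, ValueError):
    """A numeric argument violates its contract (e.g. non-positive period)."""


class InvalidBeatError(PulsevarError, ValueError):
    """A beat segment is unusable (too short, or no harmonic content)."""


class InsufficientBeatsError(PulsevarError, ValueError):
    """Fewer valid beats than the minimum required for aggregation."""


class DegenerateScoreError(PulsevarError, ZeroDivisionError):
    """A score denominator index is zero or below the epsilon guard."""

    def __init__(self, index_name: str, value: float, eps: float):
        self.index_name = index_name
        self.value = value
        self.eps = eps
        super().__init__(
            f"denominator index {index_name!r} = {value:g} is below eps={eps:g}"
        )


class InvalidBandError(PulsevarError, ValueError):
    """Two-threshold band with low >= high."""


class EmptyReportError(PulsevarError, ValueError):
    """No adopted subjects remain after exclusion."""


class UndefinedAUCError(PulsevarError, ValueError):
    """Rank AUC requested with only one class present."""


class MissingSessionError(PulsevarError, KeyError):
    """Feature assembly found subjects lacking a required session."""

    def __init__(self, subjects):
        self.subjects = list(subjects)
        super().__init__(f"missing session profiles for subjects: {self.subjects}")


class StratificationError(PulsevarError, ValueError):
    """A cross-validation fold lost one of the classes."""
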
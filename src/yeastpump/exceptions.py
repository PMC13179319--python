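"""Exception hierarchy for yeastpump."""


class YeastPumpError(ValueError):
    """Base class for all yeastpump errors."""


class ParameterDomainError(YeastPumpError):
    """Model parameters violate their domain constraints."""


class InputError(YeastPumpError):
    """Invalid numeric input (non-finite time, bad window, malformed trace)."""


class AnalyticPeakUndefinedError(YeastPumpError):
    """The closed-form peak time is undefined (s_t * t_e <= 1)."""


class UndefinedNormalizationError(YeastPumpError):
    """A normalized metric has a zero normalizer (constant or empty signal)."""


class RankDeficiencyError(YeastPumpError):
    """Calibration configurations are collinear; the plane fit is underdetermined."""


class InfeasibleDesignError(YeastPumpError):
    """Requested performance targets cannot be met inside the validity domain.

    Carries ``closest``, the nearest achievable design (a ``DesignResult``),
    so callers can report how far off the target was.
    """

    def __init__(self, message, closest=None):
        super().__init__(message)
        self.closest = closest


class ExtrapolationWarning(UserWarning):
    """Configuration lies outside the calibrated interpolation domain."""
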
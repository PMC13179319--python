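"""Three-phase CO2 production-rate model for yeast-powered pumps.

The pump rate over time is modelled as the product of three phase factors:

* **startup** — a logistic ramp capturing rehydration, metabolic adaptation
  and CO2 saturation of the medium (scale ``s_f``, steepness ``s_t``,
  latency ``t_i``);
* **stable** — an optional diauxic multiplier in (1, 2) describing the
  glucose-to-fructose shift (onset ``t_s``, transition scale ``t_ds``);
* **decline** — an exponential shutdown ``max(0, e - exp(t/t_e))`` that
  reaches exactly zero at the exhaustion time ``t_e``, which equals the pump
  runtime.

The four-parameter model omits the diauxic factor; the six-parameter model
includes it.  Peak analytics (time of maximum performance and peak rate) have
a closed form that is an analytic approximation; a deterministic numeric
search is provided alongside to validate it.

Time is measured in minutes throughout.  Rates carry an explicit unit tag
(``"uL/min"`` or ``"mL/min"``); published parameter sets are on the mL/min
scale while pump rates are conventionally quoted in uL/min, so conversion is
an explicit multiplication by 1000, never a silent guess.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit

from .exceptions import AnalyticPeakUndefinedError, InputError, ParameterDomainError

__all__ = [
    "RATE_UNITS",
    "FourParams",
    "SixParams",
    "PeakEstimate",
    "eval_startup",
    "eval_stable",
    "eval_decline",
    "eval_rate4",
    "eval_rate6",
    "eval_rate",
    "cumulative_volume",
    "peak_time",
    "peak_rate",
    "numeric_peak",
]

#: Recognized rate units, as multiplicative factors relative to uL/min.
RATE_UNITS = {"uL/min": 1.0, "mL/min": 1000.0}

#: Grid spacing (min) for the deterministic quadrature of cumulative volume.
QUADRATURE_STEP = 0.5


def _check_unit(unit: str) -> str:
    if unit not in RATE_UNITS:
        raise ParameterDomainError(
            f"unknown rate unit {unit!r}; expected one of {sorted(RATE_UNITS)}"
        )
    return unit


@dataclass(frozen=True)
class FourParams:
    """Parameters of the four-parameter pump-rate model.

    Attributes
    ----------
    s_f : float
        Rate scaling factor, in ``rate_unit`` per minute time base. Sets the
        peak activity level.
    s_t : float
        Startup steepness (1/min).
    t_i : float
        Startup latency / initiation time (min).
    t_e : float
        Exhaustion time (min); the rate is identically zero for t >= t_e and
        t_e equals the pump runtime.
    rate_unit : str
        Unit tag attached to ``s_f`` and every rate derived from it.
    """

    s_f: float
    s_t: float
    t_i: float
    t_e: float
    rate_unit: str = "uL/min"

    def __post_init__(self):
        _check_unit(self.rate_unit)
        if not all(map(math.isfinite, (self.s_f, self.s_t, self.t_i, self.t_e))):
            raise ParameterDomainError("parameters must be finite")
        if self.s_f < 0:
            raise ParameterDomainError(f"s_f must be >= 0, got {self.s_f}")
        if self.s_t <= 0:
            raise ParameterDomainError(f"s_t must be > 0, got {self.s_t}")
        if self.t_i < 0:
            raise ParameterDomainError(f"t_i must be >= 0, got {self.t_i}")
        if self.t_e <= 0:
            raise ParameterDomainError(f"t_e must be > 0, got {self.t_e}")
        if self.t_e <= self.t_i:
            raise ParameterDomainError(
                f"t_e ({self.t_e}) must exceed t_i ({self.t_i}): "
                "exhaustion must follow startup onset"
            )

    def to_unit(self, unit: str) -> "FourParams":
        """Return an equivalent parameter set with ``s_f`` expressed in `unit`."""
        _check_unit(unit)
        factor = RATE_UNITS[self.rate_unit] / RATE_UNITS[unit]
        return replace(self, s_f=self.s_f * factor, rate_unit=unit)

    def as_array(self) -> np.ndarray:
        return np.array([self.s_f, self.s_t, self.t_i, self.t_e])


@dataclass(frozen=True)
class SixParams(FourParams):
    """Four-parameter model extended with the diauxic-shift factor.

    ``t_s`` is the onset time of the glucose-to-fructose shift (min) and
    ``t_ds`` the transition steepness scale (min).
    """

    t_s: float = 0.0
    t_ds: float = 1.0

    def __post_init__(self):
        super().__post_init__()
        if not (math.isfinite(self.t_s) and math.isfinite(self.t_ds)):
            raise ParameterDomainError("diauxic parameters must be finite")
        if self.t_ds <= 0:
            raise ParameterDomainError(f"t_ds must be > 0, got {self.t_ds}")
        if not 0 < self.t_s < self.t_e:
            raise ParameterDomainError(
                f"t_s ({self.t_s}) must lie strictly inside (0, t_e={self.t_e})"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.s_f, self.s_t, self.t_i, self.t_e, self.t_s, self.t_ds])

    def drop_diauxic(self) -> FourParams:
        """The nested four-parameter model with the same startup/decline terms."""
        return FourParams(self.s_f, self.s_t, self.t_i, self.t_e, self.rate_unit)


@dataclass(frozen=True)
class PeakEstimate:
    """Numerically located performance peak: argmax time and peak rate."""

    t_max: float
    q_max: float
    rate_unit: str = "uL/min"


def eval_startup(t, p: FourParams):
    """Startup sigmoid ``s_f * logistic(s_t * (t - t_i))``.

    Defined for any real t; strictly increasing with range (0, s_f).
    Evaluated through the numerically stable logistic so large arguments do
    not overflow.
    """
    t = np.asarray(t, dtype=float)
    out = p.s_f * expit(p.s_t * (t - p.t_i))
    return out if out.ndim else float(out)


def eval_stable(t, t_s: float, t_ds: float):
    """Diauxic multiplier ``1 + 1/(1 + exp((t - t_s)/t_ds))``.

    Strictly decreasing with range (1, 2); equals 1.5 at t = t_s.
    """
    if t_ds <= 0:
        raise ParameterDomainError(f"t_ds must be > 0, got {t_ds}")
    t = np.asarray(t, dtype=float)
    out = 1.0 + expit(-(t - t_s) / t_ds)
    return out if out.ndim else float(out)


def eval_decline(t, t_e: float):
    """Decline multiplier ``max(0, e - exp(t/t_e))``.

    Zero for all t >= t_e; strictly decreasing on [0, t_e).  The exponent is
    clipped at 1 so times far beyond t_e cannot overflow (the factor is zero
    there regardless).
    """
    if t_e <= 0:
        raise ParameterDomainError(f"t_e must be > 0, got {t_e}")
    t = np.asarray(t, dtype=float)
    out = np.maximum(0.0, np.e - np.exp(np.minimum(t / t_e, 1.0)))
    return out if out.ndim else float(out)


def _check_time_nonnegative(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise InputError("times must be finite")
    if np.any(t < 0):
        raise InputError("model time starts at inoculation: t >= 0 required")
    return t


def eval_rate4(t, p: FourParams):
    """Four-parameter pump rate: startup x decline (diauxic factor omitted)."""
    t = _check_time_nonnegative(t)
    out = eval_startup(t, p) * eval_decline(t, p.t_e)
    return out if np.ndim(out) else float(out)


def eval_rate6(t, p: SixParams):
    """Six-parameter pump rate: startup x diauxic x decline."""
    t = _check_time_nonnegative(t)
    out = eval_startup(t, p) * eval_stable(t, p.t_s, p.t_ds) * eval_decline(t, p.t_e)
    return out if np.ndim(out) else float(out)


def eval_rate(t, p: FourParams):
    """Dispatch to the four- or six-parameter rate based on the parameter type."""
    if isinstance(p, SixParams):
        return eval_rate6(t, p)
    return eval_rate4(t, p)


def cumulative_volume(p: FourParams, t) -> float:
    """Cumulative produced volume V(t) = integral of the rate from 0 to t.

    Deterministic composite-trapezoid quadrature on a fixed grid of spacing
    <= 0.5 min, clipped to [0, t_e] (the integrand vanishes beyond t_e).
    Returns a float for scalar t, an array for array t.  Units are
    ``rate_unit x min`` (uL if the rate is uL/min).
    """
    t_arr = _check_time_nonnegative(t)
    scalar = t_arr.ndim == 0

    def _one(tv: float) -> float:
        upper = min(tv, p.t_e)
        if upper <= 0:
            return 0.0
        n = max(2, int(math.ceil(upper / QUADRATURE_STEP)) + 1)
        grid = np.linspace(0.0, upper, n)
        return float(np.trapezoid(eval_rate(grid, p), grid))

    if scalar:
        return _one(float(t_arr))
    return np.array([_one(tv) for tv in t_arr.ravel()]).reshape(t_arr.shape)


def peak_time(p: FourParams) -> float:
    """Closed-form time of maximum performance.

    ``t_max = t_i + ln(s_t * t_e - 1) / s_t``, the analytic approximation to
    the argmax of the four-parameter rate.  Requires ``s_t * t_e > 1``.
    """
    arg = p.s_t * p.t_e - 1.0
    if arg <= 0:
        raise AnalyticPeakUndefinedError(
            f"s_t * t_e = {p.s_t * p.t_e:.6g} <= 1: closed-form peak undefined; "
            "use numeric_peak instead"
        )
    return p.t_i + math.log(arg) / p.s_t


def peak_rate(p: FourParams) -> float:
    """Peak pump rate: the four-parameter rate evaluated at ``peak_time``.

    Returned in ``p.rate_unit``; convert with ``p.to_unit`` first if needed.
    """
    return float(eval_rate4(peak_time(p), p))


def numeric_peak(p: FourParams) -> PeakEstimate:
    """Locate the rate maximum by deterministic grid-then-refine search.

    Works for both model orders.  The search brackets the coarse argmax and
    refines until the grid step drops below 0.01 min; it validates the
    closed-form approximation, whose value can only fall below this maximum.
    """
    lo, hi = 0.0, p.t_e
    step = (hi - lo) / 2048.0
    while True:
        grid = np.arange(lo, hi + step / 2, step)
        vals = eval_rate(grid, p)
        k = int(np.argmax(vals))
        if step <= 0.01:
            return PeakEstimate(float(grid[k]), float(vals[k]), p.rate_unit)
        lo = max(0.0, grid[k] - 2 * step)
        hi = min(p.t_e, grid[k] + 2 * step)
        step = max(step / 64.0, 0.0025)
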
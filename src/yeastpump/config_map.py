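"""Two-parameter layer: pump configuration -> model parameters.

Each of the four model parameters is an affine function of the two dials a
user actually controls — yeast inoculum mass ``m`` (mg) and sucrose
concentration ``s`` (wt%):

    p(m, s) = C_m * m + C_s * s + C_0        for p in {s_f, s_t, t_i, t_e}

The twelve coefficients form a :class:`CoefficientTable`; the published
syringe-pump calibration ships as :data:`TABLE1` (s_f on the mL/min scale).
The layer supports forward prediction (peak time, peak rate, runtime),
refitting the coefficient planes from >= 3 calibrations on a new pump
design, and inverse design (find a configuration delivering a target peak
rate and runtime).

The calibration is trusted only on the closed domain m, s in [1, 5]
(mg, wt%); evaluation outside it emits :class:`ExtrapolationWarning` and
inverse design refuses to leave it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources
from math import isfinite

import numpy as np
from scipy.optimize import minimize_scalar

from .exceptions import (
    ExtrapolationWarning,
    InfeasibleDesignError,
    InputError,
    ParameterDomainError,
    RankDeficiencyError,
)
from .phase_model import FourParams, peak_rate, peak_time

__all__ = [
    "PumpConfig",
    "CoefficientTable",
    "Calibration",
    "PerformanceEstimate",
    "DesignResult",
    "TABLE1",
    "params_from_config",
    "fit_coefficients",
    "predict_performance",
    "inverse_design",
    "load_table",
    "save_table",
]

#: Closed validity domain for interpolation and design: mass (mg), sucrose (wt%).
DOMAIN_M = (1.0, 5.0)
DOMAIN_S = (1.0, 5.0)

_PARAM_NAMES = ("s_f", "s_t", "t_i", "t_e")


@dataclass(frozen=True)
class PumpConfig:
    """A pump operating condition: yeast mass m (mg), sucrose s (wt%)."""

    m: float
    s: float

    def __post_init__(self):
        if not (isfinite(self.m) and isfinite(self.s)):
            raise InputError("configuration must be finite")
        if self.m <= 0 or self.s <= 0:
            raise InputError(
                f"yeast mass and sucrose concentration must be positive, "
                f"got m={self.m}, s={self.s}"
            )

    @property
    def in_validity_domain(self) -> bool:
        return DOMAIN_M[0] <= self.m <= DOMAIN_M[1] and DOMAIN_S[0] <= self.s <= DOMAIN_S[1]


@dataclass(frozen=True)
class Calibration:
    """One calibrated condition: a configuration and its fitted parameters."""

    config: PumpConfig
    params: FourParams


@dataclass(frozen=True)
class PerformanceEstimate:
    """Forward-predicted pump performance for a configuration."""

    t_max: float      # min
    q_max: float      # uL/min
    runtime: float    # min (= t_e)


@dataclass(frozen=True)
class DesignResult:
    """Inverse-design outcome: chosen configuration and achieved performance."""

    config: PumpConfig
    achieved: PerformanceEstimate
    target_q_max: float
    target_runtime: float


@dataclass(frozen=True)
class CoefficientTable:
    """The twelve affine coefficients mapping (m, s) to the four parameters.

    Each row is ``(C_m, C_s, C_0)`` for one parameter; ``rate_unit`` is the
    scale of the s_f row.
    """

    s_f: tuple[float, float, float]
    s_t: tuple[float, float, float]
    t_i: tuple[float, float, float]
    t_e: tuple[float, float, float]
    rate_unit: str = "mL/min"

    def __post_init__(self):
        for name in _PARAM_NAMES:
            row = getattr(self, name)
            if len(row) != 3 or not all(isfinite(c) for c in row):
                raise InputError(f"coefficient row {name} must be 3 finite numbers")
        # sanity of the derived parameter planes at the domain corners
        for m in DOMAIN_M:
            for s in DOMAIN_S:
                ti = self._lin("t_i", m, s)
                te = self._lin("t_e", m, s)
                if not te > ti > 0:
                    raise ParameterDomainError(
                        f"table yields t_e={te:.4g}, t_i={ti:.4g} at (m={m}, s={s}); "
                        "need t_e > t_i > 0 across the validity domain"
                    )

    def _lin(self, name: str, m: float, s: float) -> float:
        c_m, c_s, c_0 = getattr(self, name)
        return c_m * m + c_s * s + c_0

    def evaluate(self, m: float, s: float) -> FourParams:
        """Evaluate the four parameter planes at any finite (m, s).

        The result must satisfy the model-parameter invariants; outside the
        calibrated region the planes can produce e.g. a negative s_f, which
        raises :class:`ParameterDomainError`.
        """
        if not (isfinite(m) and isfinite(s)):
            raise InputError("(m, s) must be finite")
        vals = {name: self._lin(name, m, s) for name in _PARAM_NAMES}
        return FourParams(rate_unit=self.rate_unit, **vals)


#: Published calibration of the 10 mL syringe pump (s_f on the mL/min scale).
TABLE1 = CoefficientTable(
    s_f=(0.0016218, 0.0002183, -0.0013759),
    s_t=(0.0056424, -0.0043008, 0.022460),
    t_i=(-22.551974, 8.596592, 217.890016),
    t_e=(-250.45527, 303.71105, 1262.644),
    rate_unit="mL/min",
)


def params_from_config(cfg: PumpConfig, table: CoefficientTable = TABLE1) -> FourParams:
    """Interpolate model parameters for a pump configuration.

    Outside the calibrated domain (m, s in [1, 5]) a structured
    :class:`ExtrapolationWarning` is emitted — extrapolation of the linear
    layer is unreliable — but evaluation proceeds; parameter-invariant
    violations raise.
    """
    if not cfg.in_validity_domain:
        warnings.warn(
            f"configuration (m={cfg.m} mg, s={cfg.s} wt%) is outside the "
            f"calibrated domain m in [1, 5] mg, s in [1, 5] wt%; "
            "extrapolated parameters are unreliable",
            ExtrapolationWarning,
            stacklevel=2,
        )
    return table.evaluate(cfg.m, cfg.s)


def fit_coefficients(calibrations: list[Calibration]) -> CoefficientTable:
    """Refit the twelve affine coefficients from calibrated conditions.

    Needs at least three calibrations whose configurations are not collinear
    in the (m, s) plane; with exactly three the planes interpolate them
    exactly.  Rate units of all calibrations must agree.
    """
    if len(calibrations) < 3:
        raise InputError(
            f"need at least 3 calibrations to determine the planes, got {len(calibrations)}"
        )
    units = {c.params.rate_unit for c in calibrations}
    if len(units) > 1:
        raise InputError(f"calibrations mix rate units: {sorted(units)}")
    a = np.array([[c.config.m, c.config.s, 1.0] for c in calibrations])
    if np.linalg.matrix_rank(a, tol=1e-9 * max(1.0, float(np.abs(a).max()))) < 3:
        raise RankDeficiencyError(
            "calibration configurations are collinear in the (m, s) plane; "
            "the coefficient planes are underdetermined"
        )
    rows = {}
    for name in _PARAM_NAMES:
        b = np.array([getattr(c.params, name) for c in calibrations])
        coef, *_ = np.linalg.lstsq(a, b, rcond=None)
        rows[name] = tuple(float(v) for v in coef)
    return CoefficientTable(rate_unit=units.pop(), **rows)


def predict_performance(cfg: PumpConfig, table: CoefficientTable = TABLE1) -> PerformanceEstimate:
    """Predict peak time (min), peak rate (uL/min) and runtime (min)."""
    p = params_from_config(cfg, table)
    t_max = peak_time(p)
    q_max = peak_rate(p.to_unit("uL/min"))
    return PerformanceEstimate(t_max=t_max, q_max=q_max, runtime=p.t_e)


def _q_max_at(m: float, s: float, table: CoefficientTable) -> float:
    return peak_rate(table.evaluate(m, s).to_unit("uL/min"))


def inverse_design(
    target_q_max: float,
    target_runtime: float,
    table: CoefficientTable = TABLE1,
    q_tol: float = 0.02,
) -> DesignResult:
    """Find the configuration delivering a target peak rate and runtime.

    Mirrors the experimental control strategy: pick the yeast mass that sets
    the peak rate, then pick the sucrose level that sets the runtime (the
    t_e plane is affine in s, so that step is closed-form).  Because the
    peak rate depends weakly on sucrose too, the two stages are repeated to
    a fixed point; the first pass uses the domain-midpoint sucrose level.
    Designs outside m, s in [1, 5] are refused with the closest achievable
    point attached to the error.

    ``q_tol`` is the accepted relative miss on the peak-rate target.
    """
    if not (target_q_max > 0 and target_runtime > 0):
        raise InputError("targets must be positive")

    c_m, c_s, c_0 = table.t_e
    if c_s == 0:
        raise InputError("t_e plane has no sucrose dependence; runtime not tunable")

    s = 0.5 * (DOMAIN_S[0] + DOMAIN_S[1])  # nominal sucrose for the first pass
    m = 0.5 * (DOMAIN_M[0] + DOMAIN_M[1])
    for _ in range(50):
        res = minimize_scalar(
            lambda mm: abs(_q_max_at(mm, s, table) - target_q_max),
            bounds=DOMAIN_M,
            method="bounded",
            options={"xatol": 1e-10},
        )
        m_new = float(res.x)
        s_new = (target_runtime - c_m * m_new - c_0) / c_s
        s_new_clipped = float(np.clip(s_new, *DOMAIN_S))
        if abs(m_new - m) < 1e-8 and abs(s_new_clipped - s) < 1e-8:
            m, s, s_unclipped = m_new, s_new_clipped, s_new
            break
        m, s = m_new, s_new_clipped
        s_unclipped = s_new
    cfg = PumpConfig(m, s)
    achieved = predict_performance(cfg, table)
    result = DesignResult(cfg, achieved, target_q_max, target_runtime)

    runtime_ok = abs(s_unclipped - s) < 1e-9
    q_ok = abs(achieved.q_max - target_q_max) <= q_tol * target_q_max
    if not runtime_ok:
        raise InfeasibleDesignError(
            f"target runtime {target_runtime:.6g} min requires sucrose "
            f"{s_unclipped:.4g} wt%, outside [1, 5]; closest achievable runtime "
            f"is {achieved.runtime:.6g} min",
            closest=result,
        )
    if not q_ok:
        raise InfeasibleDesignError(
            f"target peak rate {target_q_max:.6g} uL/min unreachable within "
            f"m in [1, 5] mg (closest: {achieved.q_max:.6g} uL/min at m={m:.4g})",
            closest=result,
        )
    return result


def load_table(path=None) -> CoefficientTable:
    """Load a coefficient table from JSON (default: the packaged calibration).

    Keys: ``C_msf, C_ssf, C_sf, C_mst, C_sst, C_st, C_mti, C_sti, C_ti,
    C_mte, C_ste, C_te`` plus optional ``rate_unit``.
    """
    if path is None:
        text = resources.files("yeastpump").joinpath("data/table1.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = json.loads(text)
    try:
        rows = {
            name: (raw[f"C_m{name.replace('_', '')}"],
                   raw[f"C_s{name.replace('_', '')}"],
                   raw[f"C_{name.replace('_', '')}"])
            for name in _PARAM_NAMES
        }
    except KeyError as exc:
        raise InputError(f"coefficient file missing key {exc}") from exc
    return CoefficientTable(rate_unit=raw.get("rate_unit", "mL/min"), **rows)


def save_table(table: CoefficientTable, path) -> None:
    """Write a coefficient table as the 12-key JSON dialect."""
    out = {"rate_unit": table.rate_unit}
    for name in _PARAM_NAMES:
        short = name.replace("_", "")
        c_m, c_s, c_0 = getattr(table, name)
        out[f"C_m{short}"] = c_m
        out[f"C_s{short}"] = c_s
        out[f"C_{short}"] = c_0
    with open(path, "w") as fh:
        json.dump(out, fh, indent=1)
        fh.write("\n")
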
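"""Kymograph displacement processing and hydraulic back-pressure.

Pump output is measured by time-lapse imaging of the piston: a kymograph
line profile yields piston position in pixels every few minutes.  With a
volumetric calibration (uL per pixel) the displacement series becomes a
cumulative-volume trace, from which mean flow rates over any window follow.
The pressure needed to push a given flow through a microchannel comes from
the Hagen-Poiseuille relation ``dp = 8 mu Q L / (pi R^4)``; all four inputs
are required explicitly — the package assumes no channel geometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import isfinite, pi

import numpy as np

from .exceptions import InputError
from .traces import Trace

__all__ = [
    "DisplacementTrace",
    "HydraulicSpec",
    "displacement_to_volume",
    "mean_flow_rate",
    "required_pressure",
    "ul_per_min_to_m3_per_s",
]

#: Unit conversion: 1 uL/min in m^3/s.
UL_PER_MIN_IN_M3_PER_S = 1e-9 / 60.0


def ul_per_min_to_m3_per_s(q_ul_min: float) -> float:
    return q_ul_min * UL_PER_MIN_IN_M3_PER_S


@dataclass
class DisplacementTrace:
    """Piston displacement extracted from a kymograph.

    positions are pixels (sub-pixel values allowed); ``calibration`` is the
    displaced volume per pixel (uL/px).
    """

    times: np.ndarray
    positions: np.ndarray
    calibration: float  # uL per pixel

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.calibration <= 0 or not isfinite(self.calibration):
            raise InputError(f"calibration must be > 0 uL/px, got {self.calibration}")
        if self.times.ndim != 1 or self.times.shape != self.positions.shape:
            raise InputError("times and positions must be 1-D arrays of equal length")
        if len(self.times) < 2:
            raise InputError("need at least 2 samples")
        if not np.all(np.diff(self.times) > 0):
            raise InputError("times must be strictly increasing")


def displacement_to_volume(d: DisplacementTrace) -> Trace:
    """Convert piston displacement to a cumulative-volume trace (uL).

    volume(t) = (position(t) - position(t0)) * calibration; the first sample
    is zero by construction.
    """
    volume = (d.positions - d.positions[0]) * d.calibration
    return Trace(d.times.copy(), volume, kind="volume", unit="uL")


def mean_flow_rate(d: DisplacementTrace, t_start: float, t_end: float) -> float:
    """Average flow rate (uL/min) over [t_start, t_end].

    ``(V(t_end) - V(t_start)) / (t_end - t_start)`` with linear
    interpolation of the volume at the window edges.
    """
    if not t_start < t_end:
        raise InputError(f"need t_start < t_end, got [{t_start}, {t_end}]")
    if t_start < d.times[0] or t_end > d.times[-1]:
        raise InputError(
            f"window [{t_start}, {t_end}] outside trace span "
            f"[{d.times[0]}, {d.times[-1]}]"
        )
    vol = displacement_to_volume(d)
    v0 = float(np.interp(t_start, vol.times, vol.values))
    v1 = float(np.interp(t_end, vol.times, vol.values))
    return (v1 - v0) / (t_end - t_start)


@dataclass(frozen=True)
class HydraulicSpec:
    """Inputs of the Hagen-Poiseuille pressure calculation (SI units).

    mu: dynamic viscosity (Pa s); length: channel length (m); radius:
    circular cross-section radius (m); q: flow rate (m^3/s) — use
    :meth:`from_flow_ul_min` for uL/min convenience.
    """

    mu: float
    length: float
    radius: float
    q: float

    def __post_init__(self):
        for name in ("mu", "length", "radius"):
            v = getattr(self, name)
            if not (isfinite(v) and v > 0):
                raise InputError(f"{name} must be finite and > 0, got {v}")
        if not (isfinite(self.q) and self.q >= 0):
            raise InputError(f"q must be finite and >= 0, got {self.q}")

    @classmethod
    def from_flow_ul_min(cls, mu: float, q_ul_min: float, length: float,
                         radius: float) -> "HydraulicSpec":
        return cls(mu=mu, length=length, radius=radius,
                   q=ul_per_min_to_m3_per_s(q_ul_min))


def required_pressure(h: HydraulicSpec) -> float:
    """Pressure (Pa) to sustain laminar flow through the channel:
    ``8 mu Q L / (pi R^4)``."""
    return 8.0 * h.mu * h.q * h.length / (pi * h.radius ** 4)
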
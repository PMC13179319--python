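"""Seeded synthetic pump traces and calibration grids.

The experimental kymograph traces behind the published model are not
deposited, so every pipeline stage is exercised on synthetic data that
emulate them: rates sampled every 3 min (the imaging cadence) over the full
run [0, t_e], six replicates per condition with parameter-level biological
jitter, additive Gaussian measurement noise on the rate scaled to the peak,
and optional pixel quantization when a volume trace is requested.

Defaults represent the study conditions: dt = 3 min, n = 6 replicates,
rate noise 4% of peak, replicate coefficient of variation 5%.  The noise
model is phenomenological — the published figures show only min-max
envelopes — and every knob is overridable through :class:`NoiseSpec`.
All outputs are pure functions of (inputs, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .config_map import Calibration, CoefficientTable, PumpConfig
from .exceptions import InputError
from .phase_model import FourParams, SixParams, eval_rate
from .traces import Trace

__all__ = [
    "NoiseSpec",
    "generate_trace",
    "generate_replicates",
    "generate_calibration_grid",
]

DEFAULT_DT = 3.0       # min, imaging cadence
DEFAULT_REPLICATES = 6


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model for synthetic traces.

    rate_sigma_frac: additive Gaussian sigma on the rate, as a fraction of
    the peak model rate.  replicate_cv: lognormal coefficient of variation
    of the per-replicate parameter jitter.  pixel_quantum: if set, volume
    traces are quantized to this step (uL per pixel).  seed: master seed;
    replicate i uses seed + i.
    """

    rate_sigma_frac: float = 0.04
    replicate_cv: float = 0.05
    pixel_quantum: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.rate_sigma_frac < 0 or self.replicate_cv < 0:
            raise InputError("noise fractions must be >= 0")
        if self.pixel_quantum is not None and self.pixel_quantum <= 0:
            raise InputError("pixel_quantum must be > 0")

    @staticmethod
    def silent(seed: int = 0) -> "NoiseSpec":
        return NoiseSpec(rate_sigma_frac=0.0, replicate_cv=0.0, seed=seed)


def _sample_times(p: FourParams, dt: float) -> np.ndarray:
    if dt <= 0:
        raise InputError(f"dt must be > 0, got {dt}")
    return np.arange(0.0, p.t_e + 2 * dt + dt / 2, dt)


def _trace_from_rng(p: FourParams, dt: float, noise: NoiseSpec,
                    rng: np.random.Generator, kind: str) -> Trace:
    times = _sample_times(p, dt)
    rate = eval_rate(times, p)
    if noise.rate_sigma_frac > 0:
        sigma = noise.rate_sigma_frac * float(rate.max())
        rate = rate + rng.normal(0.0, sigma, size=rate.shape)
    if kind == "rate":
        return Trace(times, rate, kind="rate", unit=p.rate_unit)
    volume = cumulative_trapezoid(rate, times, initial=0.0)
    if noise.pixel_quantum:
        volume = np.round(volume / noise.pixel_quantum) * noise.pixel_quantum
    unit = p.rate_unit.split("/")[0]
    return Trace(times, volume, kind="volume", unit=unit)


def generate_trace(p: FourParams, dt: float = DEFAULT_DT,
                   noise: NoiseSpec = NoiseSpec(), kind: str = "rate") -> Trace:
    """One synthetic trace sampled every ``dt`` min over [0, t_e + 2 dt].

    ``kind="volume"`` integrates the (noisy) rate and optionally quantizes
    to pixels.  Identical seeds give bit-identical traces.
    """
    if kind not in ("rate", "volume"):
        raise InputError(f"kind must be 'rate' or 'volume', got {kind!r}")
    rng = np.random.default_rng(noise.seed)
    return _trace_from_rng(p, dt, noise, rng, kind)


def _jitter_params(p: FourParams, cv: float, rng: np.random.Generator) -> FourParams:
    """Multiplicative lognormal jitter with the given CV on every parameter."""
    if cv == 0:
        return p
    sigma = np.sqrt(np.log1p(cv * cv))
    names = ("s_f", "s_t", "t_i", "t_e") + (
        ("t_s", "t_ds") if isinstance(p, SixParams) else ()
    )
    factors = np.exp(rng.normal(-sigma * sigma / 2.0, sigma, size=len(names)))
    updates = {n: getattr(p, n) * f for n, f in zip(names, factors)}
    return replace(p, **updates)


def generate_replicates(p: FourParams, n: int = DEFAULT_REPLICATES,
                        dt: float = DEFAULT_DT, noise: NoiseSpec = NoiseSpec(),
                        kind: str = "rate") -> list[Trace]:
    """``n`` replicate traces with per-replicate parameter jitter.

    Replicate i derives its own generator from ``seed + i`` (parameter
    jitter first, then measurement noise), so any replicate can be
    regenerated in isolation.
    """
    if n < 1:
        raise InputError(f"n must be >= 1, got {n}")
    out = []
    for i in range(n):
        rng = np.random.default_rng(noise.seed + i)
        p_i = _jitter_params(p, noise.replicate_cv, rng)
        out.append(_trace_from_rng(p_i, dt, noise, rng, kind))
    return out


def generate_calibration_grid(table: CoefficientTable, configs: list[PumpConfig],
                              noise: NoiseSpec = NoiseSpec()) -> list[Calibration]:
    """Synthetic calibrations: table-derived parameters, optionally jittered.

    Feeds coefficient-recovery tests; with zero noise the downstream plane
    fit must reproduce the generating table exactly.  Configurations must
    lie inside the calibrated domain.
    """
    out = []
    for i, cfg in enumerate(configs):
        if not cfg.in_validity_domain:
            raise InputError(
                f"config (m={cfg.m}, s={cfg.s}) outside the validity domain"
            )
        rng = np.random.default_rng(noise.seed + i)
        p = _jitter_params(table.evaluate(cfg.m, cfg.s), noise.replicate_cv, rng)
        out.append(Calibration(cfg, p))
    return out
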
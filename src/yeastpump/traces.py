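"""Time-series container for pump measurements and its CSV/JSON plumbing.

A :class:`Trace` holds either an instantaneous CO2 production / pump rate
series (kind ``"rate"``) or a cumulative pumped-volume series (kind
``"volume"``), with strictly increasing times in minutes and an explicit
unit tag.  CSV layout is two columns ``time_min,value``; the kind and unit
travel out-of-band (a CLI flag or a function argument), mirroring how
kymograph exports carry no unit metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InputError

__all__ = ["Trace", "read_trace_csv", "write_trace_csv", "mean_trace"]

_KINDS = ("rate", "volume")

#: Fraction of the observed span by which a volume trace may locally decrease
#: before it is rejected (measurement noise slack).
VOLUME_MONOTONE_SLACK = 0.02


@dataclass
class Trace:
    """A time-ordered series of rate or cumulative-volume samples."""

    times: np.ndarray
    values: np.ndarray
    kind: str = "rate"
    unit: str = "uL/min"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in _KINDS:
            raise InputError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise InputError("times and values must be 1-D arrays of equal length")
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise InputError("times must be strictly increasing")
        if not (np.all(np.isfinite(self.times)) and np.all(np.isfinite(self.values))):
            raise InputError("times and values must be finite")
        if self.kind == "volume" and len(self.values) >= 2:
            span = float(self.values.max() - self.values.min())
            drop = float(np.minimum(np.diff(self.values), 0).min(initial=0.0))
            if span > 0 and -drop > VOLUME_MONOTONE_SLACK * span:
                raise InputError(
                    "volume trace decreases by more than the allowed "
                    f"measurement slack ({VOLUME_MONOTONE_SLACK:.0%} of span)"
                )

    def __len__(self) -> int:
        return len(self.times)

    @property
    def span(self) -> float:
        return float(self.times[-1] - self.times[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_min": self.times, "value": self.values})


def read_trace_csv(path, kind: str = "rate", unit: str | None = None) -> Trace:
    """Read a two-column ``time_min,value`` CSV into a :class:`Trace`.

    Unsorted or duplicated times are rejected rather than silently sorted.
    """
    df = pd.read_csv(path)
    missing = {"time_min", "value"} - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing column(s) {sorted(missing)}")
    if unit is None:
        unit = "uL/min" if kind == "rate" else "uL"
    return Trace(df["time_min"].to_numpy(), df["value"].to_numpy(), kind=kind, unit=unit)


def write_trace_csv(trace: Trace, path, sidecar: bool = False) -> None:
    """Write a trace as ``time_min,value`` CSV, optionally with a JSON sidecar
    (``<path>.meta.json``) declaring kind and unit."""
    trace.to_frame().to_csv(path, index=False)
    if sidecar:
        meta = {"kind": trace.kind, "unit": trace.unit}
        Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))


def mean_trace(traces: list[Trace]) -> Trace:
    """Pointwise mean of replicate traces sharing a common time grid.

    Offered as the pre-step for fitting a condition mean rather than a single
    replicate.
    """
    if not traces:
        raise InputError("need at least one trace")
    first = traces[0]
    for tr in traces[1:]:
        if tr.kind != first.kind or tr.unit != first.unit:
            raise InputError("replicates must share kind and unit")
        if len(tr) != len(first) or not np.allclose(tr.times, first.times):
            raise InputError("replicates must share a common time grid")
    values = np.mean([tr.values for tr in traces], axis=0)
    return Trace(first.times.copy(), values, kind=first.kind, unit=first.unit)
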
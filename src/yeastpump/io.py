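"""JSON readers/writers for model-parameter files.

Layout: ``{"model": "four"|"six", "s_f": ..., "s_t": ..., "t_i": ...,
"t_e": ..., ["t_s": ..., "t_ds": ...,] "rate_unit": "mL/min"|"uL/min"}``.
The unit tag is mandatory on read — published parameter sets are on the
mL/min scale while pump rates are quoted in uL/min, and a silent guess
would be off by a factor of 1000.
"""

from __future__ import annotations

import json
from dataclasses import asdict

from .exceptions import InputError
from .phase_model import FourParams, SixParams

__all__ = ["read_params", "write_params", "params_from_dict", "params_to_dict"]


def params_from_dict(raw: dict) -> FourParams:
    if "rate_unit" not in raw:
        raise InputError("parameter file must declare 'rate_unit' explicitly")
    model = raw.get("model", "six" if "t_s" in raw else "four")
    try:
        if model == "four":
            return FourParams(raw["s_f"], raw["s_t"], raw["t_i"], raw["t_e"],
                              raw["rate_unit"])
        if model == "six":
            return SixParams(raw["s_f"], raw["s_t"], raw["t_i"], raw["t_e"],
                             raw["rate_unit"], t_s=raw["t_s"], t_ds=raw["t_ds"])
    except KeyError as exc:
        raise InputError(f"parameter file missing key {exc}") from exc
    raise InputError(f"model must be 'four' or 'six', got {model!r}")


def params_to_dict(p: FourParams) -> dict:
    d = asdict(p)
    d["model"] = "six" if isinstance(p, SixParams) else "four"
    return d


def read_params(path) -> FourParams:
    """Read and validate a parameter file."""
    with open(path) as fh:
        return params_from_dict(json.load(fh))


def write_params(p: FourParams, path) -> None:
    """Write a parameter file; numeric values round-trip exactly through
    JSON's decimal representation."""
    with open(path, "w") as fh:
        json.dump(params_to_dict(p), fh, indent=1)
        fh.write("\n")
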
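import numpy as np
import pytest

from yeastpump import FourParams, SixParams, TABLE1


@pytest.fixture(scope="session")
def base_params():
    """Fitted parameters of the standard condition (5 mg yeast, 5 wt% sucrose),
    on the published mL/min scale."""
    return FourParams(0.007291, 0.026052, 159.6, 1599.6, "mL/min")


@pytest.fixture(scope="session")
def sucrose3_params():
    """Fitted parameters of the 5 mg / 3 wt% sucrose condition."""
    return FourParams(0.007545, 0.026433, 140.7833, 1002.617, "mL/min")


@pytest.fixture(scope="session")
def base_six(base_params):
    """Six-parameter variant of the base condition with a pronounced diauxic dip."""
    return SixParams(
        base_params.s_f, base_params.s_t, base_params.t_i, base_params.t_e,
        base_params.rate_unit, t_s=700.0, t_ds=40.0,
    )


@pytest.fixture(scope="session")
def table1():
    return TABLE1


def random_valid_params(rng: np.random.Generator, unit: str = "mL/min") -> FourParams:
    """A realistic random draw of four-parameter sets (scale of the published
    fits: s_f ~ 0.004-0.012 mL/min, runs of 10-30 h)."""
    return FourParams(
        s_f=rng.uniform(0.004, 0.012),
        s_t=rng.uniform(0.015, 0.04),
        t_i=rng.uniform(80, 250),
        t_e=rng.uniform(600, 1800),
        rate_unit=unit,
    )
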
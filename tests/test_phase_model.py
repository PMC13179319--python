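"""Phase factors, composite rates, cumulative volume and peak analytics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from yeastpump import (
    AnalyticPeakUndefinedError,
    FourParams,
    InputError,
    ParameterDomainError,
    SixParams,
    cumulative_volume,
    eval_decline,
    eval_rate4,
    eval_rate6,
    eval_stable,
    eval_startup,
    numeric_peak,
    peak_rate,
    peak_time,
)

# -- random but realistic parameter draws for property checks ---------------

valid_params = st.builds(
    FourParams,
    s_f=st.floats(1e-4, 0.02),
    s_t=st.floats(5e-3, 0.08),
    t_i=st.floats(0.0, 400.0),
    t_e=st.floats(500.0, 2500.0),
)

valid_six = st.builds(
    lambda p, ts_frac, t_ds: SixParams(
        p.s_f, p.s_t, p.t_i, p.t_e, p.rate_unit,
        t_s=ts_frac * p.t_e, t_ds=t_ds,
    ),
    p=valid_params,
    ts_frac=st.floats(0.05, 0.95),
    t_ds=st.floats(1.0, 200.0),
)


class TestParameterValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(s_f=-0.001, s_t=0.02, t_i=100, t_e=1000),
            dict(s_f=0.007, s_t=0.0, t_i=100, t_e=1000),
            dict(s_f=0.007, s_t=0.02, t_i=-1, t_e=1000),
            dict(s_f=0.007, s_t=0.02, t_i=100, t_e=0.0),
            dict(s_f=0.007, s_t=0.02, t_i=1000, t_e=900),  # exhaustion before onset
            dict(s_f=float("nan"), s_t=0.02, t_i=100, t_e=1000),
        ],
    )
    def test_invalid_four_params_rejected(self, kwargs):
        with pytest.raises(ParameterDomainError):
            FourParams(**kwargs)

    @pytest.mark.parametrize(
        "t_s,t_ds",
        [(0.0, 10.0), (1000.0, 10.0), (1500.0, 10.0), (500.0, 0.0), (500.0, -5.0)],
    )
    def test_invalid_six_params_rejected(self, t_s, t_ds):
        with pytest.raises(ParameterDomainError):
            SixParams(0.007, 0.02, 100, 1000, t_s=t_s, t_ds=t_ds)

    def test_unit_conversion_is_factor_1000(self, base_params):
        ul = base_params.to_unit("uL/min")
        assert ul.s_f == pytest.approx(base_params.s_f * 1000, rel=1e-15)
        assert ul.to_unit("mL/min").s_f == pytest.approx(base_params.s_f, rel=1e-15)
        # time parameters untouched
        assert ul.t_i == base_params.t_i and ul.t_e == base_params.t_e


class TestStartupFactor:
    def test_logistic_midpoint_is_half_scale(self, base_params):
        assert eval_startup(base_params.t_i, base_params) == pytest.approx(
            base_params.s_f / 2
        )

    def test_saturation_limits(self, base_params):
        assert eval_startup(1e9, base_params) == pytest.approx(base_params.s_f)
        assert eval_startup(-1e9, base_params) == pytest.approx(0.0, abs=1e-300)

    def test_value_at_peak_time_matches_arithmetic(self, base_params):
        # independent arithmetic: s_f / (1 + exp(-s_t (t - t_i)))
        t = 301.84
        z = base_params.s_t * (t - base_params.t_i)
        expected = base_params.s_f / (1.0 + math.exp(-z))
        assert eval_startup(t, base_params) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.0071159, abs=1e-6)

    def test_overflow_safe_for_extreme_arguments(self, base_params):
        huge = eval_startup(np.array([1e7, -1e7]), base_params)
        assert np.all(np.isfinite(huge))


class TestStableFactor:
    def test_midpoint_and_offset_values(self):
        assert eval_stable(700.0, 700.0, 40.0) == pytest.approx(1.5)
        assert eval_stable(740.0, 700.0, 40.0) == pytest.approx(1 + 1 / (1 + math.e))

    def test_limits(self):
        assert eval_stable(1e9, 700.0, 40.0) == pytest.approx(1.0)
        assert eval_stable(-1e9, 700.0, 40.0) == pytest.approx(2.0)

    def test_nonpositive_steepness_rejected(self):
        with pytest.raises(ParameterDomainError):
            eval_stable(10.0, 700.0, 0.0)


class TestDeclineFactor:
    def test_initial_and_terminal_values(self):
        assert eval_decline(0.0, 1000.0) == pytest.approx(math.e - 1)
        assert eval_decline(1000.0, 1000.0) == 0.0
        assert eval_decline(5000.0, 1000.0) == 0.0

    def test_half_life_point(self):
        assert eval_decline(1000.0 * math.log(2), 1000.0) == pytest.approx(math.e - 2)

    def test_nonpositive_exhaustion_rejected(self):
        with pytest.raises(ParameterDomainError):
            eval_decline(10.0, -1.0)


class TestCompositeRates:
    def test_base_case_rate_at_peak_is_printed_value(self, base_params):
        # 0.010749... mL/min == 10.75 uL/min at the worked-example peak time
        assert eval_rate4(301.84, base_params) * 1000 == pytest.approx(10.75, abs=0.01)

    def test_zero_beyond_exhaustion_and_zero_scale(self, base_params):
        t = np.linspace(base_params.t_e, base_params.t_e * 3, 50)
        assert np.all(eval_rate4(t, base_params) == 0.0)
        flat = FourParams(0.0, 0.02, 100, 1000)
        assert np.all(eval_rate4(np.linspace(0, 1000, 100), flat) == 0.0)

    def test_negative_time_rejected_by_rate_not_factors(self, base_params):
        with pytest.raises(InputError):
            eval_rate4(-1.0, base_params)
        eval_startup(-1.0, base_params)  # phase factor accepts any real t

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(p=valid_six, frac=st.floats(0.0, 1.2))
    def test_rate6_equals_product_of_factors(self, p, frac):
        t = frac * p.t_e
        expected = (
            eval_startup(t, p) * eval_stable(t, p.t_s, p.t_ds) * eval_decline(t, p.t_e)
        )
        assert eval_rate6(t, p) == pytest.approx(expected, rel=1e-12, abs=1e-300)

    def test_rate6_with_distant_diauxic_onset_doubles_rate4(self, base_params):
        # diauxic factor -> 2 when the onset is far in the future
        p6 = SixParams(
            base_params.s_f, base_params.s_t, base_params.t_i, base_params.t_e,
            base_params.rate_unit, t_s=base_params.t_e * (1 - 1e-12), t_ds=1e-6,
        )
        t = np.linspace(0, base_params.t_e * 0.99, 200)
        np.testing.assert_allclose(
            eval_rate6(t, p6), 2.0 * eval_rate4(t, base_params), rtol=1e-9
        )

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(p=valid_six, frac=st.floats(0.0, 1.5))
    def test_factor_ranges(self, p, frac):
        # open intervals mathematically; the boundary is attained only when
        # the logistic argument saturates double precision
        t = frac * p.t_e
        assert 0.0 <= eval_startup(t, p) <= p.s_f
        if abs(p.s_t * (t - p.t_i)) < 30:
            assert 0.0 < eval_startup(t, p) < p.s_f
        assert 1.0 <= eval_stable(t, p.t_s, p.t_ds) <= 2.0
        if abs((t - p.t_s) / p.t_ds) < 30:
            assert 1.0 < eval_stable(t, p.t_s, p.t_ds) < 2.0
        assert 0.0 <= eval_decline(t, p.t_e) <= math.e - 1


class TestCumulativeVolume:
    def test_zero_at_origin_and_monotone(self, base_params):
        assert cumulative_volume(base_params, 0.0) == 0.0
        ts = np.linspace(0, base_params.t_e * 1.2, 25)
        vols = cumulative_volume(base_params, ts)
        assert np.all(np.diff(vols) >= 0)

    def test_constant_after_exhaustion(self, base_params):
        v_end = cumulative_volume(base_params, base_params.t_e)
        assert cumulative_volume(base_params, base_params.t_e * 2) == pytest.approx(
            v_end, rel=1e-12
        )

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_fine_trapezoid_oracle(self, seed):
        from conftest import random_valid_params

        p = random_valid_params(np.random.default_rng(seed))
        fine = np.arange(0.0, p.t_e + 0.05 / 2, 0.05)
        oracle = np.trapezoid(eval_rate4(fine, p), fine)
        assert cumulative_volume(p, p.t_e) == pytest.approx(oracle, rel=1e-3)

    def test_nonfinite_time_rejected(self, base_params):
        with pytest.raises(InputError):
            cumulative_volume(base_params, float("nan"))


class TestPeakAnalytics:
    def test_base_case_worked_example(self, base_params):
        assert peak_time(base_params) == pytest.approx(301.84, abs=0.01)
        assert peak_rate(base_params.to_unit("uL/min")) == pytest.approx(10.75, abs=0.01)

    def test_sucrose3_worked_example(self, sucrose3_params):
        # the closed form gives 263.3106 from these parameters (printed: 263.30)
        assert peak_time(sucrose3_params) == pytest.approx(263.30, abs=0.02)
        assert peak_rate(sucrose3_params.to_unit("uL/min")) == pytest.approx(
            10.30, abs=0.01
        )

    def test_forced_log_argument(self):
        # s_t * t_e = 1 + e makes the log term exactly 1
        s_t = (1 + math.e) / 1000.0
        p = FourParams(0.007, s_t, 100.0, 1000.0)
        assert peak_time(p) == pytest.approx(100.0 + 1.0 / s_t, rel=1e-12)

    def test_undefined_when_product_below_one(self):
        p = FourParams(0.007, 9e-4, 100.0, 1000.0)  # s_t * t_e = 0.9
        with pytest.raises(AnalyticPeakUndefinedError):
            peak_time(p)

    @pytest.mark.parametrize("case", ["base", "sucrose3"])
    def test_numeric_peak_validates_closed_form(self, case, base_params, sucrose3_params):
        p = base_params if case == "base" else sucrose3_params
        est = numeric_peak(p)
        closed_t = peak_time(p)
        assert p.t_i < est.t_max < p.t_e
        assert abs(est.t_max - closed_t) / closed_t < 0.05
        # closed form evaluates the rate off-argmax: never above the true max
        assert peak_rate(p) <= est.q_max + 1e-9

    def test_scaling_leaves_argmax_unchanged(self, base_params):
        import dataclasses

        scaled = dataclasses.replace(base_params, s_f=base_params.s_f * 7.3)
        assert numeric_peak(scaled).t_max == pytest.approx(
            numeric_peak(base_params).t_max, abs=0.02
        )
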
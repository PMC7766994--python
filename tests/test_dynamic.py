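import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coldkin.arrhenius import ArrheniusModel
from coldkin.dynamic import (
    effective_rate,
    effective_temperature,
    predict_method1,
    predict_method2,
)
from coldkin.profiles import TemperatureProfile, TemperatureStep, make_isothermal, make_var_scenario

MODEL = ArrheniusModel(k_ref=2e-3, ea=65_900.0, t_ref=-18.0)

profile_strategy = st.lists(
    st.tuples(st.floats(0.2, 40.0), st.floats(-22.0, -3.0)),
    min_size=1,
    max_size=6,
).map(lambda pairs: TemperatureProfile([TemperatureStep(d, T) for d, T in pairs]))


class TestEffectiveRate:
    def test_isothermal_equals_rate_at(self):
        p = make_isothermal(-8.0, 30.0)
        assert effective_rate(MODEL, p) == pytest.approx(MODEL.rate_at(-8.0), rel=1e-14)

    def test_var_cycle_matches_riemann_oracle(self):
        p = make_var_scenario(1)
        dt = 1e-4
        ts = np.arange(0.0, p.total_duration, dt) + dt / 2.0
        oracle = np.mean([MODEL.rate_at(p.temperature_at(t)) for t in ts])
        assert effective_rate(MODEL, p) == pytest.approx(oracle, rel=1e-10)

    def test_truncation_within_first_step(self):
        p = make_var_scenario(1)  # starts with -12 C for 1 d
        assert effective_rate(MODEL, p, until=0.5) == pytest.approx(
            MODEL.rate_at(-12.0), rel=1e-14
        )

    def test_nonpositive_until_rejected(self):
        with pytest.raises(ValueError):
            effective_rate(MODEL, make_isothermal(-8.0, 10.0), until=0.0)

    @given(profile_strategy)
    @settings(max_examples=40, deadline=None)
    def test_permutation_invariance(self, profile):
        shuffled = TemperatureProfile(tuple(reversed(profile.steps)))
        assert effective_rate(MODEL, profile) == pytest.approx(
            effective_rate(MODEL, shuffled), rel=1e-12
        )


class TestEffectiveTemperature:
    def test_isothermal_identity(self):
        p = make_isothermal(-8.0, 30.0)
        assert effective_temperature(MODEL, p) == pytest.approx(-8.0, abs=1e-10)

    def test_var_cycle_matches_root_solve_oracle(self):
        from scipy.optimize import brentq

        p = make_var_scenario(24)
        keff = effective_rate(MODEL, p)
        oracle = brentq(lambda T: MODEL.rate_at(T) - keff, -12.0, -5.0, xtol=1e-12)
        teff = effective_temperature(MODEL, p)
        assert teff == pytest.approx(oracle, abs=1e-9)
        # warmer than the time-weighted mean: the Arrhenius average overweights
        # the warm excursions
        assert teff > p.time_weighted_mean_temperature()

    @given(profile_strategy)
    @settings(max_examples=40, deadline=None)
    def test_bounded_by_profile_extremes(self, profile):
        teff = effective_temperature(MODEL, profile)
        temps = [s.temperature for s in profile.steps]
        assert min(temps) - 1e-9 <= teff <= max(temps) + 1e-9

    def test_undefined_for_zero_ea(self):
        flat = ArrheniusModel(k_ref=1e-3, ea=0.0)
        with pytest.raises(ValueError):
            effective_temperature(flat, make_isothermal(-8.0, 10.0))


class TestPredictions:
    def test_isothermal_sensory_crosses_limit_at_shelf_life(self):
        # zero-order decline at the -15 C rate implied by a 415-day shelf life
        model = ArrheniusModel(k_ref=4.0 / 415.0, ea=65_110.0, t_ref=-15.0)
        p = make_isothermal(-15.0, 420.0)
        trace = predict_method1(
            model, p, order="zero", y0=9.0, at_times=[415.0], direction="decreasing"
        )
        assert trace.values[0] == pytest.approx(5.0, abs=1e-9)

    def test_time_zero_returns_initial_value(self):
        trace = predict_method1(
            MODEL, make_var_scenario(1), order="first", y0=6.8, at_times=[0.0],
            direction="increasing",
        )
        assert trace.values[0] == 6.8

    def test_first_order_closed_form_at_constant_temperature(self):
        # exponential rise 6.8 -> 15 in exactly 182 days at the step's own rate
        k = math.log(15.0 / 6.8) / 182.0
        model = ArrheniusModel(k_ref=k, ea=65_790.0, t_ref=-8.0)
        trace = predict_method2(
            model, make_isothermal(-8.0, 200.0), order="first", y0=6.8,
            at_times=[182.0], direction="increasing",
        )
        assert trace.values[0] == pytest.approx(15.0, rel=1e-12)

    @given(profile_strategy, st.sampled_from(["zero", "first"]))
    @settings(max_examples=50, deadline=None)
    def test_methods_agree_on_piecewise_constant_profiles(self, profile, order):
        direction = "increasing" if order == "first" else "decreasing"
        y0 = 6.8 if order == "first" else 9.0
        times = np.linspace(0.0, profile.total_duration, 7)
        m1 = predict_method1(
            MODEL, profile, order=order, y0=y0, at_times=times, direction=direction
        )
        m2 = predict_method2(
            MODEL, profile, order=order, y0=y0, at_times=times, direction=direction
        )
        np.testing.assert_allclose(m1.values, m2.values, rtol=1e-9)

    def test_dt_subdivision_is_inert(self):
        p = make_var_scenario(3)
        times = np.linspace(0.0, p.total_duration, 5)
        coarse = predict_method2(
            MODEL, p, order="first", y0=6.8, at_times=times, direction="increasing", dt=0.5
        )
        fine = predict_method2(
            MODEL, p, order="first", y0=6.8, at_times=times, direction="increasing", dt=0.05
        )
        np.testing.assert_allclose(coarse.values, fine.values, rtol=1e-12)

    def test_method2_final_value_permutation_invariant(self):
        p = make_var_scenario(2)
        q = TemperatureProfile(tuple(reversed(p.steps)))
        end = [p.total_duration]
        vp = predict_method2(MODEL, p, order="first", y0=6.8, at_times=end, direction="increasing")
        vq = predict_method2(MODEL, q, order="first", y0=6.8, at_times=end, direction="increasing")
        assert vp.values[0] == pytest.approx(vq.values[0], rel=1e-9)

    def test_sensory_clamped_at_scale_floor(self):
        p = make_isothermal(-5.0, 400.0)
        model = ArrheniusModel(k_ref=4.0 / 134.0, ea=65_110.0, t_ref=-5.0)
        trace = predict_method2(
            model, p, order="zero", y0=9.0, at_times=[400.0], direction="decreasing", floor=1.0
        )
        assert trace.values[0] == 1.0

    def test_warming_every_step_moves_quality_monotonically(self):
        base = make_var_scenario(4)
        warm = TemperatureProfile(
            [TemperatureStep(s.duration, s.temperature + 1.0) for s in base.steps]
        )
        t = [base.total_duration]
        tvbn_base = predict_method1(MODEL, base, order="first", y0=6.8, at_times=t,
                                    direction="increasing").values[0]
        tvbn_warm = predict_method1(MODEL, warm, order="first", y0=6.8, at_times=t,
                                    direction="increasing").values[0]
        assert tvbn_warm > tvbn_base
        sens_base = predict_method1(MODEL, base, order="zero", y0=9.0, at_times=t,
                                    direction="decreasing").values[0]
        sens_warm = predict_method1(MODEL, warm, order="zero", y0=9.0, at_times=t,
                                    direction="decreasing").values[0]
        assert sens_warm < sens_base

    def test_invalid_y0_rejected(self):
        with pytest.raises(ValueError):
            predict_method1(
                MODEL, make_isothermal(-8.0, 10.0), order="first", y0=0.0, at_times=[1.0],
                direction="increasing",
            )

    def test_teff_reported_along_method1_trace(self):
        p = make_var_scenario(2)
        trace = predict_method1(
            MODEL, p, order="first", y0=6.8, at_times=[0.0, 2.0, 7.0], direction="increasing"
        )
        assert math.isnan(trace.teff[0])
        assert -12.0 <= trace.teff[1] <= -5.0
        assert -12.0 <= trace.teff[2] <= -5.0
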
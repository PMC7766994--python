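import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import coldkin as ck
from coldkin.primary import PrimaryKinetics, QualitySeries
from coldkin.synthetic import generate_isothermal, make_preset


def series(index, times, values, **kw):
    return QualitySeries(index=index, times=times, values=values, **kw)


class TestZeroOrder:
    def test_exact_line_recovered(self):
        t = np.arange(0.0, 301.0, 50.0)
        s = series("overall_acceptability", t, 9.0 - 0.01 * t, temperature=-15.0)
        fit = ck.fit_zero_order(s)
        assert fit.k == pytest.approx(0.01, abs=1e-12)
        assert fit.y0 == pytest.approx(9.0, abs=1e-10)
        assert fit.rsquared == pytest.approx(1.0)

    def test_sensory_rate_from_shelf_life_recovered(self):
        # zero-order decline 9 -> 5 over 134 days
        k = 4.0 / 134.0
        t = np.linspace(0.0, 134.0, 8)
        fit = ck.fit_zero_order(series("overall_acceptability", t, 9.0 - k * t, temperature=-5.0))
        assert fit.k == pytest.approx(k, rel=1e-12)

    def test_constant_series_flat_fit(self):
        s = series("L_value", np.arange(5.0), np.full(5, 60.0), temperature=-8.0)
        fit = ck.fit_zero_order(s)
        assert fit.k == 0.0
        assert fit.rsquared == 0.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            ck.fit_zero_order(series("L_value", [0.0, 1.0], [60.0, 59.0], temperature=-8.0))

    @given(c=st.floats(-50.0, 50.0))
    @settings(max_examples=25, deadline=None)
    def test_affine_equivariance(self, c):
        t = np.linspace(0.0, 100.0, 6)
        v = 60.0 - 0.05 * t + np.sin(t / 7.0)  # fixed wiggle, no RNG
        base = ck.fit_zero_order(series("L_value", t, v, temperature=-5.0))
        shifted = ck.fit_zero_order(series("L_value", t, v + c, temperature=-5.0))
        assert shifted.k == pytest.approx(base.k, rel=1e-9)
        assert shifted.y0 == pytest.approx(base.y0 + c, rel=1e-9, abs=1e-9)


class TestFirstOrder:
    def test_exact_exponential_recovered(self):
        k = np.log(15.0 / 6.8) / 130.0
        t = np.linspace(0.0, 130.0, 6)
        fit = ck.fit_first_order(series("TVBN", t, 6.8 * np.exp(k * t), temperature=-5.0))
        assert fit.k == pytest.approx(k, rel=1e-12)
        assert fit.y0 == pytest.approx(6.8, rel=1e-12)
        assert fit.rsquared == pytest.approx(1.0)

    def test_constant_positive_series(self):
        fit = ck.fit_first_order(series("TVBN", np.arange(5.0), np.full(5, 7.0), temperature=-8.0))
        assert fit.k == 0.0

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            ck.fit_first_order(series("TVBN", [0.0, 1.0, 2.0], [1.0, 0.0, 2.0], temperature=-8.0))

    @given(c=st.floats(0.1, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_equivariance(self, c):
        t = np.linspace(0.0, 100.0, 6)
        v = 6.8 * np.exp(0.006 * t)
        base = ck.fit_first_order(series("TVBN", t, v, temperature=-5.0))
        scaled = ck.fit_first_order(series("TVBN", t, c * v, temperature=-5.0))
        assert scaled.k == pytest.approx(base.k, rel=1e-9, abs=1e-12)
        assert scaled.y0 == pytest.approx(c * base.y0, rel=1e-9)


class TestOrderSelection:
    def test_exact_exponential_selects_first(self):
        k = 0.01
        t = np.linspace(0.0, 200.0, 8)
        assert ck.select_order(series("TVBN", t, 6.8 * np.exp(k * t), temperature=-5.0)) == "first"

    def test_exact_line_selects_zero(self):
        t = np.linspace(0.0, 200.0, 8)
        assert (
            ck.select_order(series("overall_acceptability", t, 9.0 - 0.02 * t, temperature=-5.0))
            == "zero"
        )

    def test_noisy_tvbn_mostly_selected_first(self):
        # Monte-Carlo oracle at the generator's noise: the exponential wins a
        # clear majority (measured ~0.7 over 300 seeds; curvature over
        # 6.8 -> 15 mg N/100 g is mild relative to the replicate noise).
        preset = make_preset("sea_bream")
        hits = 0
        n = 150
        for seed in range(n):
            ds = generate_isothermal(
                preset, temperatures=[-5.0], n_points=8, seed=seed, indices=["TVBN"]
            )
            if ck.select_order(ds.series("TVBN", -5.0)) == "first":
                hits += 1
        assert hits / n > 0.6


class TestNoGrowth:
    def test_flat_noisy_counts_usually_not_significant(self):
        rng = np.random.default_rng(42)
        n_not = 0
        reps = 150
        for _ in range(reps):
            t = np.linspace(0.0, 400.0, 8)
            v = 4.4 + rng.normal(0.0, 0.2, 8)
            if not ck.no_growth_test(series("TVC", t, v, temperature=-8.0)).significant:
                n_not += 1
        assert n_not / reps >= 0.9

    def test_increasing_line_is_significant(self):
        t = np.linspace(0.0, 300.0, 6)
        res = ck.no_growth_test(series("TVC", t, 4.0 + 0.01 * t, temperature=-5.0))
        assert res.significant
        assert res.slope == pytest.approx(0.01, rel=1e-9)

    def test_constant_counts_not_significant(self):
        res = ck.no_growth_test(series("TVC", np.arange(6.0), np.full(6, 4.4), temperature=-8.0))
        assert res.slope == pytest.approx(0.0, abs=1e-12)
        assert not res.significant

    def test_requires_four_points(self):
        with pytest.raises(ValueError):
            ck.no_growth_test(series("TVC", [0.0, 1.0, 2.0], [4.0, 4.1, 4.2], temperature=-8.0))


class TestSeriesValidation:
    def test_sensory_outside_scale_rejected(self):
        with pytest.raises(ValueError):
            series("taste", [0.0, 1.0, 2.0], [9.5, 8.0, 7.0], temperature=-5.0)

    def test_non_increasing_times_rejected(self):
        with pytest.raises(ValueError):
            series("TVBN", [0.0, 1.0, 1.0], [7.0, 8.0, 9.0], temperature=-5.0)

    def test_zero_time_variance_rejected_at_fit(self):
        s = series("TVBN", [5.0], [7.0], temperature=-5.0)
        with pytest.raises(ValueError):
            ck.fit_zero_order(s)

    def test_unknown_index_needs_direction(self):
        s = series("peroxide", [0.0, 1.0, 2.0], [1.0, 2.0, 3.0], temperature=-5.0)
        with pytest.raises(ValueError):
            PrimaryKinetics(s)
        assert PrimaryKinetics(s, direction="increasing").fit("zero").k > 0


class TestMeasurementsIO:
    def test_round_trip_and_replicate_averaging(self, tmp_path):
        preset = make_preset("sea_bream")
        ds = generate_isothermal(preset, n_points=6, seed=3)
        path = tmp_path / "meas.csv"
        ds.to_csv(path)
        df = ck.read_measurements(path)
        s = ck.series_from_measurements(df, "TVBN", -8.0, "sea_bream")
        assert s.n == 6
        assert s.temperature == -8.0

    def test_unknown_index_rejected(self, tmp_path):
        import pandas as pd

        path = tmp_path / "bad.csv"
        pd.DataFrame(
            {
                "product": ["x"],
                "index": ["mystery"],
                "temperature_C": [-5.0],
                "time_days": [0.0],
                "value": [1.0],
            }
        ).to_csv(path, index=False)
        with pytest.raises(ValueError):
            ck.read_measurements(path)
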
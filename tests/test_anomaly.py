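"""Detrending and the standardized event-anomaly metric."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from extremeimpact import (
    AnnualSeries,
    DegenerateVarianceError,
    DetrendSpec,
    InvalidInputError,
    MissingDataError,
    detrend_constant,
    detrend_linear,
    detrend_moving_average,
    extract_month,
    standardized_anomaly,
)
from _oracles import detrend_moving_average_oracle, standardized_anomaly_oracle


class TestAnnualSeries:
    def test_rejects_decreasing_years(self):
        with pytest.raises(InvalidInputError):
            AnnualSeries([2001, 2000], [1.0, 2.0])

    def test_rejects_gap_unless_flagged(self):
        with pytest.raises(MissingDataError):
            AnnualSeries([2000, 2002], [1.0, 2.0])
        s = AnnualSeries([2000, 2002], [1.0, 2.0], allow_gaps=True)
        assert len(s) == 2

    def test_rejects_non_finite(self):
        with pytest.raises(InvalidInputError):
            AnnualSeries([2000, 2001], [1.0, np.nan])


class TestDetrendLinear:
    def test_exact_line_gives_zero_residuals(self, linear_series):
        resid, slope, intercept = detrend_linear(linear_series)
        assert slope == pytest.approx(2.0, abs=1e-12)
        np.testing.assert_allclose(resid.values, 0.0, atol=1e-9)

    def test_constant_series_flat(self):
        resid, slope, _ = detrend_linear(AnnualSeries([1, 2, 3, 4], [7.0] * 4))
        assert slope == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(resid.values, 0.0, atol=1e-12)

    def test_hand_ols_example(self):
        # t=[0,1,2,3], y=[0,1,0,1]: slope 0.2, intercept 0.2
        resid, slope, intercept = detrend_linear(
            AnnualSeries([0, 1, 2, 3], [0.0, 1.0, 0.0, 1.0])
        )
        assert slope == pytest.approx(0.2, abs=1e-12)
        assert intercept == pytest.approx(0.2, abs=1e-12)
        np.testing.assert_allclose(resid.values, [-0.2, 0.6, -0.6, 0.2], atol=1e-12)

    def test_residuals_sum_to_zero(self, random_series):
        resid, *_ = detrend_linear(random_series())
        assert abs(resid.values.sum()) < 1e-9

    def test_too_short(self):
        with pytest.raises(InvalidInputError):
            detrend_linear(AnnualSeries([2000, 2001], [1.0, 2.0]))


class TestDetrendMovingAverage:
    def test_linear_series_zero_residuals(self, linear_series):
        resid = detrend_moving_average(linear_series, 7)
        np.testing.assert_allclose(resid.values, 0.0, atol=1e-9)

    @pytest.mark.parametrize("window", [3, 5, 7, 9, 11])
    def test_matches_brute_force_and_preserves_length(self, window, random_series):
        s = random_series(n=17)
        resid = detrend_moving_average(s, window)
        assert len(resid) == len(s)
        expected = detrend_moving_average_oracle(list(s.values), window)
        np.testing.assert_allclose(resid.values, expected, atol=1e-9)

    def test_spec_pattern_window7(self):
        values = [1.0, 2.0, 4.0, 2.0, 1.0, 2.0, 4.0, 2.0, 1.0]
        s = AnnualSeries(np.arange(2000, 2009), values)
        resid = detrend_moving_average(s, 7)
        expected = detrend_moving_average_oracle(values, 7)
        np.testing.assert_allclose(resid.values, expected, atol=1e-12)

    def test_even_window_rejected(self, linear_series):
        with pytest.raises(InvalidInputError):
            detrend_moving_average(linear_series, 4)


class TestDetrendConstant:
    def test_hand_example(self):
        resid = detrend_constant(AnnualSeries(np.arange(5), [10, 12, 8, 10, 5]))
        np.testing.assert_allclose(resid.values, [1, 3, -1, 1, -4], atol=1e-12)
        assert abs(resid.values.sum()) < 1e-12

    def test_single_value(self):
        resid = detrend_constant(AnnualSeries([2000], [4.0]))
        np.testing.assert_allclose(resid.values, [0.0])


class TestStandardizedAnomaly:
    def test_constant_detrend_hand_example(self):
        s = AnnualSeries(np.arange(2000, 2005), [10, 12, 8, 10, 5])
        res = standardized_anomaly(s, 2004, DetrendSpec("constant"))
        assert res.raw_deviation == pytest.approx(-4.0, abs=1e-12)
        assert res.sigma_value == pytest.approx(np.std([1, 3, -1, 1], ddof=1), abs=1e-12)
        assert res.anomaly_sigma == pytest.approx(-4.0 / 1.632993161855452, abs=1e-9)

    def test_zero_event_residual_gives_zero_anomaly(self):
        # event value equals the series mean -> zero residual -> zero anomaly
        values = [4.0, 6.0, 5.0, 7.0, 3.0, 5.0]
        s = AnnualSeries(np.arange(2000, 2006), values)
        res = standardized_anomaly(s, 2005, DetrendSpec("constant"))
        assert res.raw_deviation == pytest.approx(0.0, abs=1e-12)
        assert res.anomaly_sigma == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_variance_raises(self):
        s = AnnualSeries(np.arange(2000, 2006), [3, 3, 3, 3, 3, 9])
        with pytest.raises(DegenerateVarianceError):
            standardized_anomaly(s, 2005, DetrendSpec("constant"))

    def test_event_year_missing(self, random_series):
        with pytest.raises(InvalidInputError):
            standardized_anomaly(random_series(), 1900)

    def test_sigma_window_restricts_pool(self, random_series):
        s = random_series(n=32, start=1979)
        full = standardized_anomaly(s, 2003, DetrendSpec("linear"))
        short = standardized_anomaly(s, 2003, DetrendSpec("linear"), sigma_years=(2000, 2010))
        assert short.n_sigma_years == 10  # 2000..2010 minus the event year
        assert full.n_sigma_years == 31
        expected = standardized_anomaly_oracle(
            s.years.tolist(), s.values.tolist(), 2003, "linear", sigma_years=(2000, 2010)
        )
        assert short.anomaly_sigma == pytest.approx(expected, abs=1e-9)

    def test_fit_excludes_event_flag(self):
        years = np.arange(1990, 2000)
        values = 2.0 + 0.5 * (years - 1990)
        values = values.astype(float)
        values[[2, 5, 7]] += [0.4, -0.4, 0.2]
        values[-1] -= 5.0  # event
        s = AnnualSeries(years, values)
        incl = standardized_anomaly(s, 1999, DetrendSpec("linear"))
        excl = standardized_anomaly(s, 1999, DetrendSpec("linear"), fit_excludes_event=True)
        # excluding the event from the fit must make the event residual more negative
        assert excl.raw_deviation < incl.raw_deviation
        assert excl.fit_excludes_event

    @given(
        a=st.floats(min_value=0.01, max_value=50),
        b=st.floats(min_value=-100, max_value=100),
        method=st.sampled_from(["linear", "constant"]),
        data=st.data(),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_affine_invariance(self, a, b, method, data):
        """Anomaly is invariant under y -> a*y + b for a > 0."""
        values = data.draw(
            st.lists(
                st.floats(min_value=-50, max_value=50),
                min_size=8,
                max_size=20,
            )
        )
        values = np.asarray(values)
        if np.std(np.asarray(values)[:-1], ddof=1) < 1e-3:
            values = values + np.sin(np.arange(len(values)))  # avoid degenerate sigma
        years = np.arange(1990, 1990 + len(values))
        s1 = AnnualSeries(years, values)
        s2 = AnnualSeries(years, a * values + b)
        try:
            r1 = standardized_anomaly(s1, int(years[-1]), DetrendSpec(method))
        except DegenerateVarianceError:
            return
        r2 = standardized_anomaly(s2, int(years[-1]), DetrendSpec(method))
        assert r2.anomaly_sigma == pytest.approx(r1.anomaly_sigma, abs=1e-9, rel=1e-9)

    def test_sign_shared_between_raw_and_sigma_units(self, random_series):
        for _ in range(20):
            s = random_series()
            res = standardized_anomaly(s, 2003)
            assert np.sign(res.raw_deviation) == np.sign(res.anomaly_sigma) or (
                res.raw_deviation == 0 and res.anomaly_sigma == 0
            )

    def test_event_exclusion_from_sigma(self):
        """Making the event arbitrarily extreme must not change sigma when the
        mean window and fit exclude it."""
        years = np.arange(2000, 2010)
        base = np.array([5, 6, 4, 5.5, 6.5, 4.5, 5, 6, 4.8, 5.0])
        sigmas = []
        for shock in (0.0, -50.0, -5000.0):
            values = base.copy()
            values[-1] += shock
            s = AnnualSeries(years, values)
            res = standardized_anomaly(
                s, 2009, DetrendSpec("constant"), fit_excludes_event=True
            )
            sigmas.append(res.sigma_value)
        assert sigmas[0] == pytest.approx(sigmas[1], abs=1e-12)
        assert sigmas[0] == pytest.approx(sigmas[2], abs=1e-9)


class TestExtractMonth:
    def _daily(self, year, month, values):
        idx = pd.date_range(f"{year}-{month:02d}-01", periods=len(values), freq="D")
        return pd.Series(values, index=idx)

    def test_constant_august(self):
        s = self._daily(2001, 8, [2.0] * 31)
        out = extract_month(s, 8)
        assert out.years.tolist() == [2001]
        assert out.values[0] == pytest.approx(2.0)

    def test_two_years_means(self):
        s = pd.concat([self._daily(2001, 8, [3.0] * 31), self._daily(2002, 8, [5.0] * 31)])
        out = extract_month(s, 8)
        assert out.years.tolist() == [2001, 2002]
        np.testing.assert_allclose(out.values, [3.0, 5.0])

    def test_mean_of_1_to_31(self):
        s = self._daily(2001, 8, list(range(1, 32)))
        assert extract_month(s, 8).values[0] == pytest.approx(16.0)

    def test_missing_month_flagged(self):
        s = pd.concat(
            [self._daily(2001, 8, [1.0] * 31), self._daily(2003, 8, [2.0] * 31)]
        )
        with pytest.raises(MissingDataError):
            extract_month(s, 8)
        out = extract_month(s, 8, allow_missing=True)
        assert out.allow_gaps and out.years.tolist() == [2001, 2003]

    def test_month_out_of_range(self):
        with pytest.raises(InvalidInputError):
            extract_month(self._daily(2001, 8, [1.0]), 13)
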
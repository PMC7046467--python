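import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from thetatravel.delay import (
    asymmetry_delay,
    corrected_delay,
    cycle_conduction_delay,
    lag_to_degrees,
    mechanism_test,
    robust_slope,
)


class TestRobustSlope:
    def test_exact_line(self):
        x = np.array([0.0, 0.566, 1.132])
        y = np.array([0.0, 5.66, 11.32])
        slope, intercept, converged = robust_slope(x, y)
        assert slope == pytest.approx(10.0, abs=1e-9)
        assert converged

    def test_outlier_resistance_vs_ols(self):
        x = np.arange(8) * 0.566
        y = 10.0 * x
        y[4] += 30.0
        slope, _, converged = robust_slope(x, y)
        ols = np.polyfit(x, y, 1)[0]
        assert converged
        assert abs(slope - 10.0) < 0.5
        assert abs(ols - 10.0) > abs(slope - 10.0)

    def test_agrees_with_statsmodels_rlm(self, rng):
        # independent oracle: statsmodels RLM with the same bisquare psi
        for trial in range(10):
            x = rng.uniform(0, 3, 9)
            y = 4.0 + 7.0 * x + rng.normal(0, 0.5, 9)
            y[rng.integers(0, 9)] += rng.choice([-25.0, 25.0])
            slope, intercept, _ = robust_slope(x, y)
            X = sm.add_constant(x)
            fit = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight(c=4.685)).fit()
            assert slope == pytest.approx(fit.params[1], abs=0.15)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            robust_slope([0.0, 1.0], [0.0, 1.0])


class TestCycleConductionDelay:
    def test_exact_line_example(self):
        d = cycle_conduction_delay([0.0, 5.66, 11.32], [0.0, 0.566, 1.132])
        assert d.slope_ms_per_mm == pytest.approx(10.0, abs=1e-9)
        assert d.converged

    def test_nan_channels_dropped(self):
        d = cycle_conduction_delay([0.0, np.nan, 5.66, 11.32],
                                   [0.0, 0.3, 0.566, 1.132])
        assert d.n_channels == 3
        assert d.slope_ms_per_mm == pytest.approx(10.0, abs=1e-9)

    def test_two_channels_error(self):
        with pytest.raises(ValueError):
            cycle_conduction_delay([0.0, 5.0, np.nan], [0.0, 0.5, 1.0])


class TestAsymmetryDelay:
    def cyc(self, d_fall, d_rise):
        return {"d_falling_ms": d_fall, "d_rising_ms": d_rise}

    def test_worked_example(self):
        assert asymmetry_delay(self.cyc(70, 30), self.cyc(55, 45)) == 30.0

    def test_identical_cycles_zero(self):
        assert asymmetry_delay(self.cyc(60, 40), self.cyc(60, 40)) == 0.0

    def test_antisymmetry(self):
        a = asymmetry_delay(self.cyc(70, 30), self.cyc(55, 45))
        b = asymmetry_delay(self.cyc(55, 45), self.cyc(70, 30))
        assert a == -b


class TestCorrectedDelay:
    def _table(self, slopes, conv=True):
        n = len(slopes)
        return pd.DataFrame({
            "t_ref": np.arange(n) * 0.125,
            "period_ms": np.full(n, 125.0),
            "freq_hz": np.full(n, 8.0),
            "slope_ms_per_mm": slopes,
            "converged": np.full(n, conv),
            "n_channels": np.full(n, 6),
        })

    def test_constant_subtraction(self):
        med, per = corrected_delay(self._table([12.98] * 20),
                                   self._table([3.56] * 20))
        assert med == pytest.approx(12.98 - 3.56)

    def test_median_not_difference_of_medians(self):
        obs = self._table([10.0, 11.0, 30.0, 12.0, 13.0])
        asym = self._table([9.0, 1.0, 2.0, 8.0, 3.0])
        med, per = corrected_delay(obs, asym)
        per_cycle = np.array([1.0, 10.0, 28.0, 4.0, 10.0])
        assert med == pytest.approx(np.median(per_cycle))
        assert med != pytest.approx(
            np.median(obs.slope_ms_per_mm) - np.median(asym.slope_ms_per_mm)
        )

    def test_unconverged_rows_dropped(self):
        obs = self._table([10.0] * 5)
        asym = self._table([2.0] * 5)
        obs.loc[2, "converged"] = False
        med, per = corrected_delay(obs, asym)
        assert len(per) == 4


class TestLagToDegrees:
    @pytest.mark.parametrize("delay,freq,expected", [
        (12.00, 8.0, 34.56),
        (0.0, 8.0, 0.0),
        (10.0, 10.0, 36.00),
    ])
    def test_conversion(self, delay, freq, expected):
        assert lag_to_degrees(delay, freq) == pytest.approx(expected)

    def test_invalid_frequency(self):
        with pytest.raises(ValueError):
            lag_to_degrees(10.0, 0.0)


class TestMechanismTest:
    def _periods(self, rng, n):
        f = rng.uniform(6.5, 9.5, n)
        return 1000.0 / f

    def test_constant_frequency_inconclusive(self, rng):
        T = np.full(800, 125.0)
        delays = 9.0 + rng.normal(0, 1.0, 800)
        res = mechanism_test(delays, T, seed=0)
        assert res.classification == "inconclusive"
        assert abs(res.slope_abs) < 1e6  # finite

    def test_phase_locked_delays_classified_coupled(self, rng):
        T = self._periods(rng, 2000)
        delays = 26.36 / 360.0 * T + rng.normal(0, 0.8, T.size)
        res = mechanism_test(delays, T, seed=0)
        assert res.classification == "coupled"
        assert res.slope_abs < 0
        assert res.ci_rel[0] <= 0 <= res.ci_rel[1]

    def test_fixed_time_delays_classified_fixed(self, rng):
        T = self._periods(rng, 2000)
        delays = np.full(T.size, 9.15) + rng.normal(0, 0.8, T.size)
        res = mechanism_test(delays, T, seed=0)
        assert res.classification == "fixed"
        assert res.slope_rel > 0
        assert res.ci_abs[0] <= 0 <= res.ci_abs[1]

    def test_too_few_cycles(self):
        with pytest.raises(ValueError):
            mechanism_test(np.ones(100), np.full(100, 125.0))

    def test_correlations_bounded(self, rng):
        T = self._periods(rng, 600)
        delays = rng.normal(9.0, 2.0, 600)
        res = mechanism_test(delays, T, seed=1)
        assert abs(res.rho_abs) <= 1
        assert abs(res.rho_rel) <= 1
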
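import numpy as np
import pytest

from thetatravel.io import Recording
from thetatravel.phase import PhaseSeries, hilbert_phase
from thetatravel.travelwave import (
    coherence_matrix,
    cycle_triggered_average,
    fit_gradient,
    layer_decomposition,
    metric_vs_distance,
    phase_gradient,
    phase_locking,
    phase_offsets,
    relative_power,
    theta_band_power,
)

FS = 1000.0


def traveling_sine(n_ch=4, lag_s_per_ch=0.005, duration=30.0, amp=1.0,
                   noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(0, duration, 1 / FS)
    samples = np.vstack([
        amp * np.cos(2 * np.pi * 8 * (t - i * lag_s_per_ch))
        + noise * rng.standard_normal(t.size)
        for i in range(n_ch)
    ])
    return Recording(samples=samples, fs_hz=FS,
                     positions_mm=np.arange(n_ch) * 0.566)


class TestCycleTriggeredAverage:
    def test_noise_free_peak_lags(self):
        rec = traveling_sine()
        triggers = np.arange(1.0, 29.0, 0.125)  # true peaks of channel 0
        lags_ms, avg = cycle_triggered_average(rec, triggers)
        # search within one period: the periodic average repeats every 125 ms
        window = np.abs(lags_ms) < 62.5
        for i in range(rec.n_channels):
            peak_lag = lags_ms[window][np.argmax(avg[i][window])]
            assert peak_lag == pytest.approx(5.0 * i, abs=1.0)

    def test_reference_channel_peaks_at_center(self):
        rec = traveling_sine()
        triggers = np.arange(1.0, 29.0, 0.125)
        lags_ms, avg = cycle_triggered_average(rec, triggers)
        window = np.abs(lags_ms) < 62.5
        assert lags_ms[window][np.argmax(avg[0][window])] == pytest.approx(
            0.0, abs=1.0)

    def test_noise_averages_out(self):
        rec_clean = traveling_sine()
        rec_noisy = traveling_sine(noise=1.0)
        triggers = np.arange(1.0, 29.0, 0.125)
        _, avg_c = cycle_triggered_average(rec_clean, triggers)
        _, avg_n = cycle_triggered_average(rec_noisy, triggers)
        resid = np.sqrt(np.mean((avg_n - avg_c) ** 2))
        # residual RMS ~ sigma/sqrt(N) = 1/sqrt(224)
        assert resid < 3.0 / np.sqrt(224)


class TestPhaseOffsetsAndGradient:
    def test_imposed_offsets_recovered(self):
        t = np.arange(0, 20, 1 / FS)
        phases = {}
        for ch, off in [("a", 0.0), ("b", 15.0), ("c", 30.0)]:
            x = np.cos(2 * np.pi * 8 * t - np.deg2rad(off))
            phases[ch] = hilbert_phase(x, FS, channel=ch)
        offsets, hists = phase_offsets(phases, "a")
        assert offsets["a"] == pytest.approx(0.0, abs=0.5)
        assert offsets["b"] == pytest.approx(15.0, abs=1.0)
        assert offsets["c"] == pytest.approx(30.0, abs=1.0)

    def test_wrap_convention_beyond_180(self):
        t = np.arange(0, 20, 1 / FS)
        a = hilbert_phase(np.cos(2 * np.pi * 8 * t), FS)
        b = hilbert_phase(np.cos(2 * np.pi * 8 * t + np.deg2rad(10.0)), FS)
        offsets, _ = phase_offsets({"a": a, "b": b}, "a")
        assert offsets["b"] == pytest.approx(-10.0, abs=1.0)

    def test_exact_line(self):
        offsets = {"a": 0.0, "b": 15.0, "c": 30.0, "d": 45.0}
        positions = {"a": 0.0, "b": 0.566, "c": 1.132, "d": 1.698}
        fit = phase_gradient(offsets, positions)
        assert fit.slope == pytest.approx(26.50, abs=0.02)
        assert fit.r2 == pytest.approx(1.0)

    def test_zero_offsets_zero_slope(self):
        fit = phase_gradient({"a": 0.0, "b": 0.0, "c": 0.0},
                             {"a": 0.0, "b": 0.5, "c": 1.0})
        assert fit.slope == 0.0

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_gradient([0.0, 1.0], [0.0, 1.0])


class TestPhaseLocking:
    def test_constant_offset_is_one(self):
        a = np.linspace(0, 36000, 10_000) % 360
        assert phase_locking(a, (a + 45) % 360) == pytest.approx(1.0)

    def test_uniform_independent_phases_near_zero(self, rng):
        # E[R] ~ sqrt(pi)/(2 sqrt(n)) for uniform phases
        vals = [
            phase_locking(np.random.default_rng(s).uniform(0, 360, 10_000),
                          np.zeros(10_000))
            for s in range(10)
        ]
        assert np.mean(vals) == pytest.approx(np.sqrt(np.pi) / 2 / 100,
                                              abs=0.005)

    def test_von_mises_matches_bessel_ratio(self, rng):
        from scipy.special import i0, i1
        diffs = np.rad2deg(rng.vonmises(0.0, 2.0, 200_000))
        mrl = phase_locking(diffs, np.zeros(diffs.size))
        assert mrl == pytest.approx(i1(2) / i0(2), abs=0.01)


class TestCoherence:
    def test_identical_channels_unity(self):
        rec = traveling_sine(n_ch=3, lag_s_per_ch=0.0, duration=40.0,
                             noise=0.2, seed=1)
        rec.samples[1] = rec.samples[0]
        coh = coherence_matrix(rec)
        assert coh[0, 1] == pytest.approx(1.0, abs=1e-6)
        assert np.allclose(np.diag(coh), 1.0)

    def test_symmetry(self):
        rec = traveling_sine(duration=40.0, noise=0.5, seed=2)
        coh = coherence_matrix(rec)
        np.testing.assert_allclose(coh, coh.T, atol=1e-12)

    def test_independent_noise_low_coherence(self, rng):
        samples = rng.standard_normal((2, int(300 * FS)))
        rec = Recording(samples=samples, fs_hz=FS, positions_mm=[0.0, 0.5])
        coh = coherence_matrix(rec)
        assert coh[0, 1] < 0.1

    def test_shared_signal_intermediate_coherence(self, rng):
        # shared theta-band signal at 2:1 amplitude over independent
        # theta-band noise: per-bin msc = (4/(4+1))^2 = 0.64
        from thetatravel.phase import bandpass
        t = np.arange(0, 120, 1 / FS)
        common = bandpass(rng.standard_normal(t.size), FS, 6.0, 12.0)
        common /= common.std()
        chans = []
        for _ in range(2):
            noise = bandpass(rng.standard_normal(t.size), FS, 6.0, 12.0)
            chans.append(2.0 * common + noise / noise.std())
        rec = Recording(samples=np.vstack(chans), fs_hz=FS,
                        positions_mm=[0.0, 0.5])
        coh = coherence_matrix(rec)
        assert coh[0, 1] == pytest.approx(0.64, abs=0.12)


class TestMetricsVsDistance:
    def test_equal_power_relative_one_slope_zero(self):
        rec = traveling_sine(duration=35.0)
        power = theta_band_power(rec)
        rel = relative_power(power)
        np.testing.assert_allclose(rel, 1.0, atol=0.01)
        fit = metric_vs_distance(rel, rec.positions_mm)
        assert fit.slope == pytest.approx(0.0, abs=0.02)

    def test_linear_metric_recovered_exactly(self):
        positions = np.arange(5) * 0.566
        values = 1.0 - 0.067 * positions
        fit = metric_vs_distance(values, positions)
        assert fit.slope == pytest.approx(-0.067)
        assert fit.r2 == pytest.approx(1.0)


class TestLayerDecomposition:
    def test_constructed_correlation(self, rng):
        n = 200
        along = rng.uniform(0, 3, n)
        across = rng.uniform(0, 0.5, n)
        diffs = 26.5 * along + rng.normal(0, 5, n)
        rho_along, rho_across, _ = layer_decomposition(
            diffs, along, across, np.zeros(n, dtype=bool))
        assert rho_along > 0.9
        assert abs(rho_across) < 0.15

    def test_degenerate_input_flagged_zero(self):
        rho_along, rho_across, _ = layer_decomposition(
            np.full(10, 20.0), np.arange(10.0), np.arange(10.0),
            np.zeros(10, dtype=bool))
        assert rho_along == 0.0 and rho_across == 0.0

    def test_reversal_correction_collapses_bimodality(self, rng):
        n = 300
        along = rng.uniform(0, 3, n)
        spans = rng.uniform(0, 1, n) < 0.4
        diffs = 10.0 * along + rng.normal(0, 5, n)
        diffs[spans] += 180.0
        _, _, corrected = layer_decomposition(
            diffs, along, np.zeros(n), spans)
        raw_var = 1 - np.abs(np.mean(np.exp(1j * np.deg2rad(diffs))))
        cor_var = 1 - np.abs(np.mean(np.exp(1j * np.deg2rad(corrected))))
        assert cor_var < raw_var
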
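import numpy as np
import pandas as pd
import pytest

from thetatravel.phase import (
    circular_mean_deg,
    hilbert_phase,
    match_cycle_events,
    waveform_phase,
    wrap_deg,
)
from thetatravel.sim import warp_waveform

FS = 1000.0


def edge_trim(n, fs=FS, margin_s=1.0):
    # the analytic-signal edge transient of the 6-12 Hz filtfilt chain
    # decays below 1 degree about 1 s from the ends
    return slice(int(margin_s * fs), n - int(margin_s * fs))


class TestWrap:
    def test_wrap_convention(self):
        assert wrap_deg(350.0) == pytest.approx(-10.0)
        assert wrap_deg(-190.0) == pytest.approx(170.0)
        assert wrap_deg(180.0) == pytest.approx(180.0)

    def test_circular_mean(self):
        assert circular_mean_deg([350.0, 10.0]) == pytest.approx(0.0, abs=1e-9)


class TestHilbertPhase:
    def test_cosine_phase_is_linear(self):
        t = np.arange(0, 10, 1 / FS)
        x = np.cos(2 * np.pi * 8 * t)
        series = hilbert_phase(x, FS)
        expected = (2880.0 * t) % 360.0
        err = np.abs(wrap_deg(series.phase_deg - expected))
        assert err[edge_trim(t.size)].max() < 1.0

    def test_offset_channels_recover_45_degrees(self):
        t = np.arange(0, 10, 1 / FS)
        a = hilbert_phase(np.cos(2 * np.pi * 8 * t), FS)
        b = hilbert_phase(np.cos(2 * np.pi * 8 * t - np.pi / 4), FS)
        sl = edge_trim(t.size)
        diff = circular_mean_deg(a.phase_deg[sl] - b.phase_deg[sl])
        assert diff == pytest.approx(45.0, abs=1.0)

    def test_amplitude_modulation_tolerated(self):
        t = np.arange(0, 10, 1 / FS)
        am = 1 + 0.5 * np.sin(2 * np.pi * 1.0 * t)
        x = am * np.cos(2 * np.pi * 8 * t)
        series = hilbert_phase(x, FS)
        expected = (2880.0 * t) % 360.0
        err = np.abs(wrap_deg(series.phase_deg - expected))
        assert err[edge_trim(t.size)].max() < 2.0

    def test_amplitude_scaling_invariance(self):
        t = np.arange(0, 5, 1 / FS)
        x = np.cos(2 * np.pi * 8 * t)
        a = hilbert_phase(x, FS).phase_deg
        b = hilbert_phase(123.4 * x, FS).phase_deg
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_short_epoch_rejected(self):
        with pytest.raises(ValueError):
            hilbert_phase(np.zeros(500), FS)


class TestWaveformPhase:
    def test_pure_cosine_durations(self):
        t = np.arange(0, 20, 1 / FS)
        _, cycles = waveform_phase(np.cos(2 * np.pi * 8 * t), FS)
        assert len(cycles) > 100
        # symmetric cycle: rising (trough->next peak) and falling
        # (peak->trough) each span half the 125 ms period, as do the
        # midpoint-anchored peak and trough spans
        for col in ["d_rising_ms", "d_falling_ms"]:
            assert cycles[col].median() == pytest.approx(62.5, abs=1.5)
        core = cycles.dropna()
        for col in ["d_peak_ms", "d_trough_ms"]:
            assert core[col].median() == pytest.approx(62.5, abs=1.5)

    def test_agreement_with_hilbert_on_sinusoid(self):
        t = np.arange(0, 20, 1 / FS)
        x = np.cos(2 * np.pi * 8 * t)
        wf, _ = waveform_phase(x, FS)
        hb = hilbert_phase(x, FS)
        sl = edge_trim(t.size)
        diff = wrap_deg(wf.phase_deg[sl] - hb.phase_deg[sl])
        assert np.nanmax(np.abs(diff)) < 5.0

    def test_20hz_rhythm_yields_no_cycles(self):
        t = np.arange(0, 5, 1 / FS)
        _, cycles = waveform_phase(np.sin(2 * np.pi * 20 * t), FS)
        assert len(cycles) == 0

    def test_duration_additivity(self):
        # D_rising + D_falling = T for every cycle; peak/trough spans sum
        # to the rise-anchor spacing on stationary input
        t = np.arange(0, 30, 1 / FS)
        x = warp_waveform(360.0 * 7.973 * t, -0.3, 0.1)
        _, cycles = waveform_phase(x, FS)
        np.testing.assert_allclose(
            cycles.d_rising_ms + cycles.d_falling_ms, cycles.period_ms,
            atol=1.0 + 1e-9,
        )
        core = cycles.dropna()
        rise_spacing = 1000 * np.diff(cycles.t_rise.values)
        np.testing.assert_allclose(
            (core.d_peak_ms + core.d_trough_ms).values, rise_spacing,
            atol=1.0 + 1e-9,
        )

    def test_amplitude_scaling_invariance(self):
        t = np.arange(0, 10, 1 / FS)
        x = warp_waveform(360.0 * 8 * t, -0.2, 0.05)
        _, c1 = waveform_phase(x, FS)
        _, c2 = waveform_phase(250.0 * x, FS)
        pd.testing.assert_frame_equal(c1, c2)

    def test_session_generator_round_trip(self, synchronized_session):
        # dorsal channel configured at rise/decay -0.43: the measured
        # channel median must recover it
        cfg, rec, truth = synchronized_session
        _, cycles = waveform_phase(rec.samples[0], rec.fs_hz)
        rd = np.log10(cycles.d_rising_ms / cycles.d_falling_ms).median()
        assert rd == pytest.approx(truth.asym_rd[0], abs=0.03)


class TestMatchCycleEvents:
    def _cycles(self, t0, n=50, period=0.125):
        t_peak = t0 + period * np.arange(n)
        df = pd.DataFrame({
            "t_peak": t_peak,
            "t_fall": t_peak + 0.25 * period,
            "t_trough": t_peak + 0.5 * period,
            "t_rise": t_peak + 0.75 * period,
            "t_peak_next": t_peak + period,
        })
        df["period_ms"] = period * 1000
        df["freq_hz"] = 1.0 / period
        return df

    def test_identical_channels_zero_offsets(self):
        cyc = {ch: self._cycles(0.0) for ch in "abc"}
        table = match_cycle_events(cyc, "a", 0)
        assert np.allclose(table["b"], 0.0)
        assert np.allclose(table["c"], 0.0)

    def test_constant_shift_recovered(self):
        cyc = {"a": self._cycles(0.0), "b": self._cycles(0.010),
               "c": self._cycles(0.0)}
        table = match_cycle_events(cyc, "a", 0)
        assert np.allclose(table["b"], 10.0)

    def test_proximity_rule_wraps_to_next_cycle(self):
        # +70 ms shift on a 125 ms rhythm: nearest event belongs to the
        # next cycle, offset -55 ms
        cyc = {"a": self._cycles(0.0), "b": self._cycles(0.070),
               "c": self._cycles(0.0)}
        table = match_cycle_events(cyc, "a", 0)
        inner = table["b"].iloc[1:-1]
        assert np.allclose(inner, -55.0)

    def test_missing_channel_gives_nan(self):
        cyc = {"a": self._cycles(0.0), "b": self._cycles(0.0).iloc[:0],
               "c": self._cycles(0.0)}
        table = match_cycle_events(cyc, "a", 0)
        assert table["b"].isna().all()

    def test_needs_three_channels(self):
        cyc = {"a": self._cycles(0.0), "b": self._cycles(0.0)}
        with pytest.raises(ValueError):
            match_cycle_events(cyc, "a", 0)
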
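import numpy as np
import pytest
from scipy import signal as sps

from thetatravel.preprocess import remove_artifacts
from thetatravel.sim import (
    InfeasibleAsymmetryError,
    SimConfig,
    inject_artifacts,
    simulate_mua,
    simulate_session,
    warp_fractions,
    warp_waveform,
)

FLAT = dict(asym_rd_dorsal=0.0, asym_rd_ventral=0.0,
            asym_pt_dorsal=0.0, asym_pt_ventral=0.0)


class TestWarpWaveform:
    def test_symmetric_case_is_pure_cosine(self):
        theta = np.linspace(0, 720, 2001)
        np.testing.assert_allclose(
            warp_waveform(theta, 0.0, 0.0), np.cos(np.deg2rad(theta)),
            atol=1e-12,
        )

    def test_fraction_example(self):
        # solved numerically from the four duration-ratio equations
        f_pf, f_ft, f_tr, f_rp = warp_fractions(-0.43, 0.21)
        assert (round(f_pf, 3), round(f_ft, 3), round(f_tr, 3),
                round(f_rp, 3)) == (0.451, 0.278, 0.103, 0.168)

    def test_fractions_sum_to_one_and_match_duration_ratios(self):
        for a_rd, a_pt in [(-0.43, 0.21), (-0.11, -0.10), (0.3, 0.2)]:
            f_pf, f_ft, f_tr, f_rp = warp_fractions(a_rd, a_pt)
            assert f_pf + f_ft + f_tr + f_rp == pytest.approx(1.0)
            # rising = trough->peak span, falling = peak->trough span
            assert np.log10((f_tr + f_rp) / (f_pf + f_ft)) == pytest.approx(a_rd)
            assert np.log10((f_rp + f_pf) / (f_ft + f_tr)) == pytest.approx(a_pt)

    def test_fractions_always_positive_but_can_collapse(self):
        # the closure keeps every fraction > 0 for finite indices (e.g.
        # f_ft = D_fall * D_trough), but extreme indices shrink one toward
        # zero, which the session-config guard rejects
        f = warp_fractions(-2.0, 2.0)
        assert min(f) > 0
        assert min(f) < 0.02

    def test_anchor_values(self):
        # peak at 0 deg -> +1; trough after the falling fraction -> -1
        f_pf, f_ft, _, _ = warp_fractions(-0.3, 0.1)
        assert warp_waveform(np.array([0.0]), -0.3, 0.1)[0] == pytest.approx(1)
        trough_theta = 360.0 * (f_pf + f_ft)
        assert warp_waveform(np.array([trough_theta]), -0.3, 0.1)[0] == \
            pytest.approx(-1)


class TestSimulateSession:
    def test_synchronized_zero_gradient_channels_identical(self):
        cfg = SimConfig(mechanism="synchronized", gradient_deg_per_mm=0.0,
                        duration_s=10.0, noise_amp_uV=0.0, freq_jitter=0.0,
                        seed=0, **FLAT)
        rec, _ = simulate_session(cfg)
        for i in range(1, rec.n_channels):
            np.testing.assert_array_equal(rec.samples[i], rec.samples[0])

    def test_seed_determinism(self):
        cfg = SimConfig(duration_s=12.0, seed=7)
        rec1, _ = simulate_session(cfg)
        rec2, _ = simulate_session(SimConfig(duration_s=12.0, seed=7))
        np.testing.assert_array_equal(rec1.samples, rec2.samples)

    def test_fixed_delay_cross_correlation_lag(self):
        # closed form: shifting a periodic signal by d*x delays the
        # cross-correlation peak by G*span/(360*f)
        cfg = SimConfig(mechanism="fixed_delay", duration_s=30.0,
                        noise_amp_uV=0.0, freq_jitter=0.0, seed=0, **FLAT)
        rec, _ = simulate_session(cfg)
        span = rec.positions_mm[-1] - rec.positions_mm[0]
        expected_lag_s = cfg.gradient_deg_per_mm * span / 360.0 / 8.0
        a = rec.samples[0] - rec.samples[0].mean()
        b = rec.samples[-1] - rec.samples[-1].mean()
        corr = sps.correlate(b, a, mode="full")
        lags = sps.correlation_lags(b.size, a.size)
        window = np.abs(lags) < 0.5 / 8.0 * cfg.fs_hz  # within half a period
        lag = lags[window][np.argmax(corr[window])] / cfg.fs_hz
        assert abs(lag - expected_lag_s) <= 1.0 / cfg.fs_hz

    def test_coupled_chain_locks_at_configured_lag(self, coupled_session):
        cfg, rec, truth = coupled_session
        assert truth.locked
        phases = np.deg2rad(truth.trajectory.phase_deg[:, int(10 * cfg.fs_hz):])
        diffs = np.diff(phases, axis=0)
        mrl = np.abs(np.mean(np.exp(1j * diffs), axis=1))
        assert mrl.min() > 0.9
        mean_lag = -np.rad2deg(np.angle(np.mean(np.exp(1j * diffs))))
        target = cfg.gradient_deg_per_mm * cfg.spacing_mm
        assert mean_lag == pytest.approx(target, rel=0.10)

    def test_frequency_stays_within_band(self):
        cfg = SimConfig(duration_s=60.0, seed=3)
        _, truth = simulate_session(cfg)
        f = truth.trajectory.freq_hz
        assert f.min() >= cfg.base_freq_hz - 3 * cfg.freq_jitter
        assert f.max() <= cfg.base_freq_hz + 3 * cfg.freq_jitter

    def test_ground_truth_phase_monotone(self, coupled_session):
        _, _, truth = coupled_session
        assert np.all(np.diff(truth.trajectory.phase_deg, axis=1) >= -1e-9)

    def test_infeasible_config_rejected(self):
        with pytest.raises(InfeasibleAsymmetryError):
            SimConfig(asym_rd_dorsal=-1.5, asym_pt_dorsal=1.5)


class TestSimulateMua:
    @pytest.fixture(scope="class")
    def mua_session(self):
        cfg = SimConfig(mechanism="synchronized", duration_s=100.0,
                        fs_hz=10000.0, noise_amp_uV=50.0, freq_jitter=0.0,
                        n_channels=4, seed=5, **FLAT)
        return cfg, *simulate_session(cfg)

    def test_unmodulated_rate_matches_poisson_mean(self, mua_session):
        cfg, rec, truth = mua_session
        _, spikes = simulate_mua(rec, truth, rate0=20.0, mod_depth=0.0, seed=1)
        total = len(spikes[0])
        assert abs(total - 2000) <= 3 * np.sqrt(2000)

    def test_spikes_lock_to_local_trough(self, mua_session):
        cfg, rec, truth = mua_session
        _, spikes = simulate_mua(rec, truth, rate0=20.0, mod_depth=0.8, seed=2)
        t = truth.trajectory.times
        th = np.interp(spikes[0], t, truth.trajectory.phase_deg[0])
        mean_phase = np.rad2deg(
            np.angle(np.mean(np.exp(1j * np.deg2rad(th))))) % 360
        assert len(spikes[0]) > 1000
        assert abs(mean_phase - 180.0) < 5.0

    def test_zero_rate_leaves_trace_unchanged(self, mua_session):
        cfg, rec, truth = mua_session
        out, spikes = simulate_mua(rec, truth, rate0=0.0, seed=3)
        assert all(len(s) == 0 for s in spikes)
        np.testing.assert_array_equal(out.samples, rec.samples)

    def test_mod_depth_validated(self, mua_session):
        cfg, rec, truth = mua_session
        with pytest.raises(ValueError):
            simulate_mua(rec, truth, mod_depth=1.5)


class TestInjectArtifacts:
    def test_zero_rate_is_identity(self, coupled_session):
        _, rec, _ = coupled_session
        out, times = inject_artifacts(rec, rate_hz=0.0)
        assert times.size == 0
        np.testing.assert_array_equal(out.samples, rec.samples)

    def test_injected_event_is_masked(self, coupled_session):
        cfg, rec, _ = coupled_session
        out, times = inject_artifacts(rec, rate_hz=0.02, amp_multiple=10.0,
                                      seed=4)
        assert times.size > 0
        mask = remove_artifacts(out.samples[0], cfg.fs_hz)
        excluded = ~mask.include
        for t0 in times:
            i = int(t0 * cfg.fs_hz) + 1
            assert excluded[i]

    def test_mask_covers_injected_fraction(self, coupled_session):
        cfg, rec, _ = coupled_session
        out, times = inject_artifacts(rec, rate_hz=0.05, amp_multiple=10.0,
                                      dur_ms=20.0, seed=5)
        mask = remove_artifacts(out.samples[0], cfg.fs_hz)
        injected = times.size * 0.020 * cfg.fs_hz
        assert (~mask.include).sum() >= injected

    def test_amp_multiple_must_exceed_threshold(self, coupled_session):
        _, rec, _ = coupled_session
        with pytest.raises(ValueError):
            inject_artifacts(rec, rate_hz=0.1, amp_multiple=3.0)
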
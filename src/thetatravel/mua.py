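"""Multiunit spiking-band envelope analysis.

The 600–3000 Hz "spiking band" of the broadband extracellular signal is
dominated by multiunit action potentials.  Its amplitude envelope,
band-passed back to theta frequencies, oscillates when spiking is
theta-rhythmic; cross-correlating the envelopes across channels measures
the conduction lag of multiunit activity independently of the LFP phase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io import Recording
from .travelwave import GradientFit, fit_gradient

log = logging.getLogger(__name__)

MIN_FS_HZ = 6000.0


@dataclass
class EnvelopeSet:
    """Theta-filtered spiking-band envelopes, one row per channel."""

    envelopes: np.ndarray  # (n_channels, n_samples)
    fs_hz: float
    positions_mm: np.ndarray


def spiking_band_envelope(recording: Recording,
                          spike_band=(600.0, 3000.0),
                          theta_band=(4.0, 12.0)) -> EnvelopeSet:
    """Spiking-band amplitude envelope, theta-filtered.

    Pipeline: zero-phase 4th-order Butterworth bandpass 600–3000 Hz →
    analytic-signal magnitude → zero-phase 3rd-order Butterworth bandpass
    4–12 Hz.  Requires a sampling rate of at least 6 kHz.
    """
    if recording.fs_hz < MIN_FS_HZ:
        raise ValueError(
            f"spiking-band analysis needs fs >= {MIN_FS_HZ} Hz, "
            f"got {recording.fs_hz}"
        )
    sos_spk = sps.butter(4, spike_band, btype="bandpass", fs=recording.fs_hz,
                         output="sos")
    spk = sps.sosfiltfilt(sos_spk, recording.samples, axis=1)
    env = np.abs(sps.hilbert(spk, axis=1))
    sos_th = sps.butter(3, theta_band, btype="bandpass", fs=recording.fs_hz,
                        output="sos")
    env = sps.sosfiltfilt(sos_th, env, axis=1)
    return EnvelopeSet(envelopes=env, fs_hz=recording.fs_hz,
                       positions_mm=recording.positions_mm.copy())


def _xcorr_lag_ms(a: np.ndarray, b: np.ndarray, fs: float,
                  max_lag_ms: float):
    """Lag (ms) of the peak of the normalized cross-correlation of b vs a.

    Positive lag = ``b`` delayed relative to ``a``.  Returns (lag_ms,
    on_boundary).
    """
    a = a - a.mean()
    b = b - b.mean()
    n = a.size
    max_lag = int(round(max_lag_ms / 1000.0 * fs))
    corr = sps.correlate(b, a, mode="full", method="fft")
    corr /= n * a.std() * b.std()
    lags = np.arange(-n + 1, n)
    sel = np.abs(lags) <= max_lag
    corr, lags = corr[sel], lags[sel]
    k = int(np.argmax(corr))
    on_boundary = k == 0 or k == lags.size - 1
    return lags[k] / fs * 1000.0, on_boundary


def envelope_lags(envelope_set: EnvelopeSet, ref_index: int = 0,
                  max_lag_ms: float = 120.0):
    """Cross-correlation lag of each channel's envelope behind the
    dorsal-most channel, and the lag-vs-position regression.

    Channels whose correlogram peaks on the ±``max_lag_ms`` window boundary
    are flagged and excluded from the fit.  Needs at least 4 channels.

    Returns (lags_ms, boundary_flags, fit: GradientFit).
    """
    env = envelope_set.envelopes
    if env.shape[0] < 4:
        raise ValueError("envelope lag analysis needs >= 4 channels")
    ref = env[ref_index]
    lags = np.empty(env.shape[0])
    flags = np.zeros(env.shape[0], dtype=bool)
    for i in range(env.shape[0]):
        if i == ref_index:
            lags[i] = 0.0
            continue
        lags[i], flags[i] = _xcorr_lag_ms(ref, env[i], envelope_set.fs_hz,
                                          max_lag_ms)
        if flags[i]:
            log.warning("channel %d: correlogram peak on window boundary", i)
    ok = ~flags
    fit = fit_gradient(envelope_set.positions_mm[ok], lags[ok])
    return lags, flags, fit


def compare_mua_lfp_slopes(mua_slopes_ms_per_mm, lfp_slopes_ms_per_mm):
    """Paired comparison of MUA envelope-lag and LFP conduction-delay
    slopes across sessions (signed-rank test).

    Returns a dict with the per-session pairs, the median difference and
    the paired signed-rank statistic/p-value.
    """
    from .stats import signed_rank_test

    mua = np.asarray(mua_slopes_ms_per_mm, dtype=float)
    lfp = np.asarray(lfp_slopes_ms_per_mm, dtype=float)
    if mua.shape != lfp.shape:
        raise ValueError("need one LFP slope per MUA slope")
    w, w_max, p = signed_rank_test(mua, lfp)
    return {
        "pairs": list(zip(mua.tolist(), lfp.tolist())),
        "median_difference_ms_per_mm": float(np.median(mua - lfp)),
        "signed_rank": w,
        "signed_rank_max": w_max,
        "p_value": p,
    }
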
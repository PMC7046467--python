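"""Traveling-wave quantification across the electrode array.

Cycle-triggered averages, phase-offset distributions and their linear
gradient along the dorsoventral axis, phase locking (mean resultant
length), theta-band coherence, power-vs-distance profiles, and the
along- vs across-layer decomposition of pairwise phase differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats

from .io import Recording
from .phase import PhaseSeries, circular_mean_deg, wrap_deg

log = logging.getLogger(__name__)


@dataclass
class GradientFit:
    """OLS fit of a per-channel metric against dorsoventral distance."""

    slope: float  # units per mm
    intercept: float
    r2: float  # squared Pearson correlation
    points: list = field(default_factory=list)  # (distance_mm, value)

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def fit_gradient(distances_mm, values) -> GradientFit:
    """Least-squares line with Pearson r²; needs >= 3 points."""
    x = np.asarray(distances_mm, dtype=float)
    y = np.asarray(values, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("gradient fit needs at least 3 points")
    slope, intercept = np.polyfit(x, y, 1)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        r2 = 0.0
    else:
        r2 = float(stats.pearsonr(x, y).statistic ** 2)
    return GradientFit(slope=float(slope), intercept=float(intercept),
                       r2=r2, points=list(zip(x.tolist(), y.tolist())))


def cycle_triggered_average(recording: Recording, trigger_times_s,
                            window_ms: float = 250.0):
    """Mean raw LFP around reference-channel theta peaks.

    Averages the *unfiltered* traces in ±``window_ms`` windows around each
    trigger.  Returns (lags_ms, averages) with ``averages`` shaped
    (n_channels, n_lags).
    """
    triggers = np.asarray(trigger_times_s, dtype=float)
    fs = recording.fs_hz
    half = int(round(window_ms / 1000.0 * fs))
    idx = np.round(triggers * fs).astype(int)
    idx = idx[(idx - half >= 0) & (idx + half < recording.n_samples)]
    if idx.size < 50:
        log.warning("cycle_triggered_average: only %d triggers", idx.size)
    if idx.size == 0:
        raise ValueError("no usable triggers")
    offsets = np.arange(-half, half + 1)
    windows = recording.samples[:, idx[:, None] + offsets[None, :]]
    return offsets / fs * 1000.0, windows.mean(axis=1)


def phase_offsets(phases: dict, ref_channel: str,
                  n_hist_bins: int = 36):
    """Circular-mean theta phase lag of each channel behind a reference.

    ``phases`` maps channel id -> :class:`PhaseSeries` (Hilbert method, NaN
    outside selected epochs).  The per-sample circular difference
    ``ref − channel`` is positive when the channel lags the reference in
    time.  Returns (offsets_deg: dict, histograms: dict of (bin_edges,
    counts)).
    """
    ref = phases[ref_channel].phase_deg
    offsets, hists = {}, {}
    edges = np.linspace(-180.0, 180.0, n_hist_bins + 1)
    for ch, series in phases.items():
        diff = wrap_deg(ref - series.phase_deg)
        diff = diff[np.isfinite(diff)]
        offsets[ch] = circular_mean_deg(diff) if diff.size else np.nan
        hists[ch] = (edges, np.histogram(diff, bins=edges)[0])
    return offsets, hists


def phase_gradient(offsets: dict, positions_mm: dict) -> GradientFit:
    """Linear fit of phase offset (deg) against distance (mm)."""
    channels = list(offsets)
    return fit_gradient(
        [positions_mm[ch] for ch in channels],
        [offsets[ch] for ch in channels],
    )


def phase_locking(phase_deg_i, phase_deg_ref) -> float:
    """Mean resultant length of the circular phase-difference series."""
    diff = np.deg2rad(np.asarray(phase_deg_i, dtype=float)
                      - np.asarray(phase_deg_ref, dtype=float))
    diff = diff[np.isfinite(diff)]
    if diff.size == 0:
        return np.nan
    return float(np.abs(np.mean(np.exp(1j * diff))))


def _clean_segments(mask: np.ndarray, min_len: int):
    """[start, stop) pairs of True runs of at least ``min_len`` samples."""
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.concatenate([[0], starts])
    if mask[-1]:
        stops = np.concatenate([stops, [mask.size]])
    return [(a, b) for a, b in zip(starts, stops) if b - a >= min_len]


def coherence_matrix(recording: Recording, mask: np.ndarray | None = None,
                     band=(6.0, 12.0), window_s: float = 1.0) -> np.ndarray:
    """Pairwise magnitude-squared coherence averaged over the theta band.

    Welch cross-spectra with 1 s Hann windows and 50 % overlap (1 Hz
    resolution, matching 1 Hz frequency increments across 6–12 Hz),
    accumulated over artifact-free segments.  Not restricted to
    high-theta epochs.
    """
    fs = recording.fs_hz
    nper = int(round(window_s * fs))
    if mask is None:
        segments = [(0, recording.n_samples)]
    else:
        segments = _clean_segments(np.asarray(mask, dtype=bool), nper)
    if not segments or sum(b - a for a, b in segments) < 30 * fs:
        log.warning("coherence_matrix: fewer than 30 s of clean data")
    n_ch = recording.n_channels
    # accumulate Welch auto/cross spectra over segments, weighted by the
    # number of windows each segment contributes
    pxx_sum = None
    pxy_sum = None
    freqs = None
    for a, b in segments:
        seg = recording.samples[:, a:b]
        n_win = max(1, (seg.shape[1] - nper // 2) // (nper // 2))
        freqs, pxx = sps.welch(seg, fs=fs, nperseg=nper, noverlap=nper // 2,
                               axis=1)
        pxy = np.empty((n_ch, n_ch, freqs.size), dtype=complex)
        for i in range(n_ch):
            _, pxy[i] = sps.csd(seg[i][None, :], seg, fs=fs, nperseg=nper,
                                noverlap=nper // 2, axis=1)
        if pxx_sum is None:
            pxx_sum = n_win * pxx
            pxy_sum = n_win * pxy
        else:
            pxx_sum += n_win * pxx
            pxy_sum += n_win * pxy
    sel = (freqs >= band[0]) & (freqs <= band[1])
    coh = (np.abs(pxy_sum[:, :, sel]) ** 2
           / (pxx_sum[:, None, sel] * pxx_sum[None, :, sel]))
    return coh.mean(axis=2)


def theta_band_power(recording: Recording, mask: np.ndarray | None = None,
                     band=(6.0, 12.0)) -> np.ndarray:
    """Per-channel mean 6–12 Hz band power (µV²/Hz) on artifact-free data."""
    fs = recording.fs_hz
    nper = int(round(fs))
    if mask is None:
        x = recording.samples
    else:
        x = recording.samples[:, np.asarray(mask, dtype=bool)]
    freqs, pxx = sps.welch(x, fs=fs, nperseg=nper, noverlap=nper // 2, axis=1)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return pxx[:, sel].mean(axis=1)


def metric_vs_distance(values, positions_mm) -> GradientFit:
    """Regression of a per-channel metric (MRL, coherence with the
    reference, or relative theta power) against distance from the
    dorsal-most electrode."""
    return fit_gradient(positions_mm, values)


def relative_power(power: np.ndarray) -> np.ndarray:
    """Per-channel power divided by the across-channel mean."""
    power = np.asarray(power, dtype=float)
    return power / power.mean()


def layer_decomposition(pair_phase_diff_deg, along_mm, across_mm,
                        spans_reversal):
    """Rank correlation of pair phase differences with the two displacement
    axes after undoing the layer II/I polarity reversal.

    Pairs flagged as spanning the reversal get a 180° offset added before
    wrapping.  Returns (rho_along, rho_across, corrected_diff_deg); a
    degenerate (constant) input yields rho = 0 with a log entry.
    """
    diff = np.asarray(pair_phase_diff_deg, dtype=float).copy()
    spans = np.asarray(spans_reversal, dtype=bool)
    diff[spans] += 180.0
    diff = wrap_deg(diff)

    def _rho(x):
        x = np.asarray(x, dtype=float)
        if np.ptp(diff) == 0 or np.ptp(x) == 0:
            log.warning("layer_decomposition: degenerate input, rho set to 0")
            return 0.0
        return float(stats.spearmanr(x, diff).statistic)

    return _rho(along_mm), _rho(across_mm), diff
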
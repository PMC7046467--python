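"""Instantaneous theta-phase estimation and cycle segmentation.

Two estimators are provided.  The Hilbert method band-passes the trace to
6–12 Hz and takes the analytic-signal angle; it is the standard approach
but smooths away waveform asymmetry.  The waveform method band-passes to
1–25 Hz, anchors the phase to identified waveform landmarks — peak (0°),
falling mid-point (90°), trough (180°), rising mid-point (270°) — and
interpolates linearly in between, preserving asymmetric rise/fall timing.

Phase convention throughout: peak = 0°, falling = 90°, trough = 180°,
rising = 270°, wrapped to [0, 360); circular differences wrap to
(−180, +180].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import EpochSet

log = logging.getLogger(__name__)

#: columns of the per-cycle table produced by :func:`waveform_phase`
CYCLE_COLUMNS = [
    "t_peak", "t_fall", "t_trough", "t_rise", "t_peak_next",
    "d_rising_ms", "d_falling_ms", "d_peak_ms", "d_trough_ms",
    "period_ms", "freq_hz",
]

ANCHOR_FOR_PHASE = {0: "t_peak", 90: "t_fall", 180: "t_trough", 270: "t_rise"}

# extrema-separation rule: successive like extrema must be 83-250 ms apart
MIN_PERIOD_S = 0.083
MAX_PERIOD_S = 0.250


def wrap_deg(x):
    """Wrap circular differences (degrees) to (−180, +180]."""
    return -((-np.asarray(x, dtype=float) + 180.0) % 360.0 - 180.0)


def circular_mean_deg(x) -> float:
    """Circular mean of angles in degrees, in (−180, +180]."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    return float(wrap_deg(np.rad2deg(np.angle(np.mean(np.exp(1j * np.deg2rad(x)))))))


@dataclass
class PhaseSeries:
    """Per-sample phase in degrees [0, 360); NaN outside selected epochs."""

    phase_deg: np.ndarray
    fs_hz: float
    method: str  # 'hilbert' | 'waveform'
    channel: Optional[str] = None


def bandpass(x: np.ndarray, fs: float, lo: float, hi: float, order: int = 4,
             axis: int = -1) -> np.ndarray:
    """Zero-phase Butterworth bandpass."""
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, axis=axis)


def hilbert_phase(signal: np.ndarray, fs: float,
                  epochs: Optional[EpochSet] = None,
                  channel: Optional[str] = None) -> PhaseSeries:
    """Theta phase via the Hilbert transform of the 6–12 Hz band.

    The trace is band-passed with a zero-phase fourth-order Butterworth
    filter and the angle of the analytic signal is returned in degrees
    [0, 360), 0° at the waveform peak (cosine convention).
    """
    x = np.asarray(signal, dtype=float)
    if x.size < fs:
        raise ValueError("epoch shorter than 1 s; phase estimate skipped")
    filtered = bandpass(x, fs, 6.0, 12.0)
    phase = np.angle(sps.hilbert(filtered), deg=True) % 360.0
    if epochs is not None:
        phase = np.where(epochs.sample_mask(x.size, fs), phase, np.nan)
    return PhaseSeries(phase_deg=phase, fs_hz=fs, method="hilbert",
                       channel=channel)


def unwrap_phase_deg(phase_deg: np.ndarray) -> np.ndarray:
    """Unwrap a [0, 360) phase series in degrees, independently over each
    contiguous finite run (NaN outside selected epochs stays NaN)."""
    x = np.asarray(phase_deg, dtype=float)
    out = np.full(x.shape, np.nan)
    finite = np.isfinite(x)
    d = np.diff(finite.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if finite[0]:
        starts = [0] + starts
    if finite[-1]:
        stops = stops + [x.size]
    for a, b in zip(starts, stops):
        out[a:b] = np.rad2deg(np.unwrap(np.deg2rad(x[a:b])))
    return out


def _local_extrema(v: np.ndarray, mode: str) -> np.ndarray:
    """Strict local extrema over a 5-sample neighbourhood, earliest on ties."""
    if mode == "max":
        y = v
    else:
        y = -v
    c = np.zeros(v.size, dtype=bool)
    c[2:-2] = (
        (y[2:-2] > y[1:-3]) & (y[2:-2] >= y[3:-1])
        & (y[2:-2] >= y[:-4]) & (y[2:-2] >= y[4:])
    )
    return np.flatnonzero(c)


def _alternating_extrema(v: np.ndarray, maxima: np.ndarray,
                         minima: np.ndarray):
    """Merge extrema into a strictly alternating peak/trough sequence.

    Between two like extrema with none of the other kind in between, the
    more extreme one is kept (earlier on ties).
    """
    idx = np.concatenate([maxima, minima])
    kind = np.concatenate([np.ones(maxima.size, dtype=int),
                           -np.ones(minima.size, dtype=int)])
    order = np.argsort(idx, kind="stable")
    idx, kind = idx[order], kind[order]
    keep_idx, keep_kind = [], []
    for i, k in zip(idx, kind):
        if keep_kind and keep_kind[-1] == k:
            prev = keep_idx[-1]
            better = v[i] > v[prev] if k == 1 else v[i] < v[prev]
            if better:
                keep_idx[-1] = i
        else:
            keep_idx.append(i)
            keep_kind.append(k)
    return np.asarray(keep_idx), np.asarray(keep_kind)


def _midpoint_anchor(v: np.ndarray, i0: int, i1: int) -> int:
    """Sample in (i0, i1) whose voltage is closest to mean(v[i0], v[i1])."""
    target = 0.5 * (v[i0] + v[i1])
    seg = v[i0 + 1: i1]
    return i0 + 1 + int(np.argmin(np.abs(seg - target)))


def waveform_phase(signal: np.ndarray, fs: float,
                   epochs: Optional[EpochSet] = None,
                   channel: Optional[str] = None):
    """Waveform-based theta phase and per-cycle anchor table.

    The trace is band-passed to 1–25 Hz (zero-phase fourth-order
    Butterworth); local maxima and minima whose like-extremum separation
    falls within [83, 250] ms mark the 0° and 180° phases, and the 90°/270°
    anchors are the samples closest to the mean of the flanking extremum
    voltages.  Continuous phase is piecewise-linear between anchors.
    Extrema violating the separation rule break the cycle chain: no cycle
    is emitted there.

    Returns
    -------
    series : PhaseSeries
    cycles : pandas.DataFrame
        One row per accepted cycle with columns :data:`CYCLE_COLUMNS`.
        ``d_peak_ms``/``d_trough_ms`` need the preceding cycle's rising
        anchor and are NaN for the first cycle of each contiguous chain.
    """
    x = np.asarray(signal, dtype=float)
    filtered = bandpass(x, fs, 1.0, 25.0)
    maxima = _local_extrema(filtered, "max")
    minima = _local_extrema(filtered, "min")
    rows = []
    if maxima.size >= 2 and minima.size >= 1:
        idx, kind = _alternating_extrema(filtered, maxima, minima)
        peak_pos = np.flatnonzero(kind == 1)
        for a, b in zip(peak_pos, peak_pos[1:]):
            if b != a + 2:  # exactly one trough between successive peaks
                continue
            i_pk, i_tr, i_pk2 = idx[a], idx[a + 1], idx[b]
            period_s = (i_pk2 - i_pk) / fs
            if not MIN_PERIOD_S <= period_s <= MAX_PERIOD_S:
                continue
            i_fall = _midpoint_anchor(filtered, i_pk, i_tr)
            i_rise = _midpoint_anchor(filtered, i_tr, i_pk2)
            rows.append((i_pk, i_fall, i_tr, i_rise, i_pk2))

    cols = np.asarray(rows, dtype=float).reshape(-1, 5)
    t = cols / fs
    cycles = pd.DataFrame({
        "t_peak": t[:, 0], "t_fall": t[:, 1], "t_trough": t[:, 2],
        "t_rise": t[:, 3], "t_peak_next": t[:, 4],
    })
    cycles["d_rising_ms"] = (cycles.t_peak_next - cycles.t_trough) * 1000
    cycles["d_falling_ms"] = (cycles.t_trough - cycles.t_peak) * 1000
    contiguous = np.zeros(len(cycles), dtype=bool)
    if len(cycles) > 1:
        contiguous[1:] = np.isclose(
            cycles.t_peak.values[1:], cycles.t_peak_next.values[:-1]
        )
    t_rise_prev = np.full(len(cycles), np.nan)
    t_rise_prev[contiguous] = cycles.t_rise.values[
        np.flatnonzero(contiguous) - 1
    ]
    cycles["d_peak_ms"] = (cycles.t_fall - t_rise_prev) * 1000
    cycles["d_trough_ms"] = (cycles.t_rise - cycles.t_fall) * 1000
    cycles["period_ms"] = (cycles.t_peak_next - cycles.t_peak) * 1000
    cycles["freq_hz"] = 1000.0 / cycles["period_ms"]

    if epochs is not None and len(cycles):
        inside = epochs.contains(cycles.t_peak.values) & epochs.contains(
            cycles.t_peak_next.values
        )
        cycles = cycles[inside].reset_index(drop=True)

    phase = _interpolate_phase(cycles, x.size, fs)
    if epochs is not None:
        phase = np.where(epochs.sample_mask(x.size, fs), phase, np.nan)
    series = PhaseSeries(phase_deg=phase, fs_hz=fs, method="waveform",
                         channel=channel)
    if channel is not None:
        cycles.insert(0, "channel", channel)
    return series, cycles


def _interpolate_phase(cycles: pd.DataFrame, n: int, fs: float) -> np.ndarray:
    """Piecewise-linear phase between anchors; NaN outside cycle chains."""
    phase = np.full(n, np.nan)
    m = len(cycles)
    if m == 0:
        return phase
    t_peak = cycles.t_peak.values
    t_next = cycles.t_peak_next.values
    chain_start = np.ones(m, dtype=bool)
    chain_start[1:] = ~np.isclose(t_peak[1:], t_next[:-1])
    # cycle index within its chain -> unwrapped base phase
    start_idx = np.maximum.accumulate(
        np.where(chain_start, np.arange(m), 0)
    )
    base = 360.0 * (np.arange(m) - start_idx)
    anchor_t = np.column_stack([
        t_peak, cycles.t_fall.values, cycles.t_trough.values,
        cycles.t_rise.values,
    ]).ravel()
    anchor_p = (base[:, None] + np.array([0.0, 90.0, 180.0, 270.0])).ravel()
    chain_end = np.ones(m, dtype=bool)
    chain_end[:-1] = chain_start[1:]
    anchor_t = np.concatenate([anchor_t, t_next[chain_end]])
    anchor_p = np.concatenate([anchor_p, base[chain_end] + 360.0])
    order = np.argsort(anchor_t, kind="stable")
    anchor_t, anchor_p = anchor_t[order], anchor_p[order]
    keep = np.ones(anchor_t.size, dtype=bool)
    keep[1:] = np.diff(anchor_t) > 0
    anchor_t, anchor_p = anchor_t[keep], anchor_p[keep]

    covered = np.zeros(n, dtype=bool)
    for a, b in zip(np.ceil(t_peak * fs).astype(int),
                    np.floor(t_next * fs).astype(int) + 1):
        covered[max(a, 0):min(b, n)] = True
    grid = np.flatnonzero(covered)
    phase[grid] = np.interp(grid / fs, anchor_t, anchor_p) % 360.0
    return phase


def match_cycle_events(cycles_by_channel: dict, ref_channel: str,
                       ref_phase: int = 0) -> pd.DataFrame:
    """Per-cycle same-phase event offsets of every channel vs a reference.

    For each reference-channel anchor of ``ref_phase`` (0/90/180/270°),
    each other channel contributes its *nearest* same-phase anchor, searched
    both forward and backward in time (no directional bias); channels with
    no anchor within ±half the reference period contribute NaN.

    Returns a DataFrame with one row per reference event: columns
    ``t_ref`` (s), ``period_ms``, ``freq_hz`` and one offset column (ms,
    positive = that channel's event later than the reference) per channel.
    """
    if ref_phase not in ANCHOR_FOR_PHASE:
        raise ValueError("ref_phase must be one of 0, 90, 180, 270")
    if len(cycles_by_channel) < 3:
        raise ValueError("cycle matching needs cycles on >= 3 channels")
    col = ANCHOR_FOR_PHASE[ref_phase]
    ref = cycles_by_channel[ref_channel]
    t_ref = ref[col].values
    out = pd.DataFrame({
        "t_ref": t_ref,
        "period_ms": ref["period_ms"].values,
        "freq_hz": ref["freq_hz"].values,
    })
    half_period_s = ref["period_ms"].values / 2000.0
    for ch, cyc in cycles_by_channel.items():
        if ch == ref_channel:
            out[ch] = 0.0
            continue
        t_ch = np.sort(cyc[col].values)
        if t_ch.size == 0:
            out[ch] = np.nan
            continue
        pos = np.searchsorted(t_ch, t_ref)
        left = t_ch[np.clip(pos - 1, 0, t_ch.size - 1)]
        right = t_ch[np.clip(pos, 0, t_ch.size - 1)]
        nearest = np.where(
            np.abs(t_ref - left) <= np.abs(right - t_ref), left, right
        )
        offset_s = nearest - t_ref
        offset_s[np.abs(offset_s) > half_period_s] = np.nan
        out[ch] = offset_s * 1000.0
    return out
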
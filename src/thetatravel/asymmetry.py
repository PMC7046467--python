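"""Cycle-wise theta waveform-asymmetry indices.

The rise/decay index is log10 of the ratio between the rising-phase and
decaying(falling)-phase durations of one theta cycle; the peak/trough
index is log10 of the peak-to-trough duration ratio.  Negative rise/decay
marks a sawtooth with a fast rise and slow decay.  A channel's asymmetry
is the median index over its cycles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class AsymmetryIndex:
    rise_decay: float  # log10(D_rising / D_falling)
    peak_trough: float  # log10(D_peak / D_trough)


def cycle_asymmetry(cycle) -> AsymmetryIndex:
    """Asymmetry indices of one cycle (row of the per-cycle table).

    ``d_peak_ms``/``d_trough_ms`` may be NaN on the first cycle of a chain,
    in which case the peak/trough index is NaN; a zero duration drops the
    cycle (returns NaN indices) with a log entry.
    """
    d_rise, d_fall = cycle["d_rising_ms"], cycle["d_falling_ms"]
    d_peak, d_trough = cycle["d_peak_ms"], cycle["d_trough_ms"]
    if d_rise <= 0 or d_fall <= 0:
        log.warning("cycle with non-positive rise/fall duration dropped")
        return AsymmetryIndex(np.nan, np.nan)
    rd = float(np.log10(d_rise / d_fall))
    if not np.isfinite(d_peak) or not np.isfinite(d_trough):
        pt = np.nan
    elif d_peak <= 0 or d_trough <= 0:
        log.warning("cycle with non-positive peak/trough duration dropped")
        pt = np.nan
    else:
        pt = float(np.log10(d_peak / d_trough))
    return AsymmetryIndex(rise_decay=rd, peak_trough=pt)


def cycle_asymmetry_table(cycles: pd.DataFrame) -> pd.DataFrame:
    """Vectorized per-cycle indices; returns the table with ``rise_decay``
    and ``peak_trough`` columns appended (NaN where undefined)."""
    out = cycles.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        rd = np.log10(out["d_rising_ms"] / out["d_falling_ms"])
        pt = np.log10(out["d_peak_ms"] / out["d_trough_ms"])
    bad = (out["d_rising_ms"] <= 0) | (out["d_falling_ms"] <= 0)
    rd[bad] = np.nan
    pt[(out["d_peak_ms"] <= 0) | (out["d_trough_ms"] <= 0)] = np.nan
    out["rise_decay"] = rd
    out["peak_trough"] = pt
    return out


def channel_asymmetry(cycles: pd.DataFrame) -> AsymmetryIndex:
    """Median asymmetry over all cycles of one channel.

    The median across cycles summarizes the channel's waveform; fewer than
    100 cycles triggers a warning but the median is still computed.
    """
    table = cycle_asymmetry_table(cycles)
    n = int(table["rise_decay"].notna().sum())
    if n < 100:
        log.warning("channel_asymmetry: only %d cycles", n)
    return AsymmetryIndex(
        rise_decay=float(table["rise_decay"].median()),
        peak_trough=float(table["peak_trough"].median()),
    )
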
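"""Artifact rejection and high-amplitude theta epoch selection.

Artifacts are voltage swings exceeding five times the signal RMS; the
detector is applied iteratively to the progressively cleaned data until no
further samples are excluded, with a 500 ms buffer around every excursion.
Epochs for phase analysis are runs where the 6–12 Hz analytic-signal
envelope stays above an amplitude criterion for at least 500 ms, ignoring
sub-threshold dips of 100 ms or less.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io import EpochSet, Recording
from .phase import bandpass

log = logging.getLogger(__name__)

#: default amplitude criterion (µV) for high-amplitude theta selection,
#: referenced to a generator theta amplitude of 600 µV
DEFAULT_AMP_UV = 400.0
REFERENCE_THETA_AMP_UV = 600.0


class DegenerateSignalError(RuntimeError):
    """Artifact rejection excluded every sample."""


@dataclass
class CleanMask:
    """Per-sample inclusion flags after iterative artifact rejection."""

    include: np.ndarray  # (n_samples,) or (n_channels, n_samples) bool
    iterations: int

    @property
    def fraction_removed(self) -> float:
        return float(1.0 - np.mean(self.include))


def remove_artifacts(signal: np.ndarray, fs: float, k: float = 5.0,
                     buffer_ms: float = 500.0) -> CleanMask:
    """Iterative k×RMS artifact rejection on a single trace.

    Each pass computes the RMS over currently included samples and excludes
    samples with |v| > k×RMS together with ``buffer_ms`` before and after;
    passes repeat until a pass excludes nothing.
    """
    x = np.asarray(signal, dtype=float)
    n_buffer = int(round(buffer_ms / 1000.0 * fs))
    if x.size <= 2 * n_buffer:
        raise ValueError("signal shorter than twice the artifact buffer")
    include = np.ones(x.size, dtype=bool)
    iterations = 0
    while True:
        iterations += 1
        if not include.any():
            raise DegenerateSignalError("artifact rejection removed all samples")
        rms = np.sqrt(np.mean(x[include] ** 2))
        bad = include & (np.abs(x) > k * rms)
        if not bad.any():
            break
        # dilate each excursion by the buffer on both sides
        idx = np.flatnonzero(bad)
        starts = np.maximum(idx - n_buffer, 0)
        stops = np.minimum(idx + n_buffer + 1, x.size)
        drop = np.zeros(x.size + 1, dtype=int)
        np.add.at(drop, starts, 1)
        np.add.at(drop, stops, -1)
        include &= np.cumsum(drop[:-1]) == 0
    return CleanMask(include=include, iterations=iterations)


def remove_artifacts_recording(recording: Recording, k: float = 5.0,
                               buffer_ms: float = 500.0) -> CleanMask:
    """Per-channel artifact rejection; a sample is included only when it is
    clean on *every* channel (keeps cross-channel cycle matching defined)."""
    masks = [
        remove_artifacts(recording.samples[i], recording.fs_hz, k, buffer_ms)
        for i in range(recording.n_channels)
    ]
    per_channel = np.vstack([m.include for m in masks])
    combined = per_channel.all(axis=0)
    if not combined.any():
        raise DegenerateSignalError("artifact rejection removed all samples")
    return CleanMask(include=per_channel, iterations=max(m.iterations for m in masks))


def select_theta_epochs(signal: np.ndarray, fs: float,
                        mask: np.ndarray | None = None,
                        amp_uV: float = DEFAULT_AMP_UV,
                        min_dur_ms: float = 500.0,
                        max_gap_ms: float = 100.0) -> EpochSet:
    """High-amplitude theta epochs from one (reference) channel.

    Theta amplitude is the magnitude of the analytic signal of the 6–12 Hz
    band (zero-phase fourth-order Butterworth).  Super-threshold runs whose
    sub-threshold gaps last ``max_gap_ms`` or less are merged; runs of at
    least ``min_dur_ms`` are kept.  Samples excluded by ``mask`` count as
    sub-threshold.
    """
    x = np.asarray(signal, dtype=float)
    envelope = np.abs(sps.hilbert(bandpass(x, fs, 6.0, 12.0)))
    above = envelope >= amp_uV
    if mask is not None:
        above &= np.asarray(mask, dtype=bool)
    runs = _runs(above)
    if not runs:
        return EpochSet([])
    # merge across short gaps
    max_gap = max_gap_ms / 1000.0 * fs
    merged = [list(runs[0])]
    for a, b in runs[1:]:
        if a - merged[-1][1] <= max_gap:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    min_len = min_dur_ms / 1000.0 * fs
    intervals = [
        (a / fs, b / fs) for a, b in merged if (b - a) >= min_len
    ]
    return EpochSet(intervals)


def scaled_amplitude_criterion(theta_amp_uV: float) -> float:
    """Amplitude criterion rescaled for synthetic sessions whose configured
    theta amplitude differs from the 600 µV reference."""
    return DEFAULT_AMP_UV * theta_amp_uV / REFERENCE_THETA_AMP_UV


def _runs(flags: np.ndarray):
    """[start, stop) index pairs of True runs."""
    d = np.diff(flags.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if flags[0]:
        starts = np.concatenate([[0], starts])
    if flags[-1]:
        stops = np.concatenate([stops, [flags.size]])
    return list(zip(starts, stops))
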
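"""Reading and writing multichannel LFP recordings and pipeline tables.

On-disk dialect: a flat interleaved little-endian int16 binary ``lfp.dat``
(channel-fastest, i.e. frame-major) plus a JSON sidecar ``lfp.json`` holding
the sampling rate, channel count, µV-per-count scale, per-channel anatomical
positions (mm along the dorsoventral axis, increasing ventrally) and channel
labels.  Times are seconds from recording start; intervals are half-open
``[start, end)``.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

log = logging.getLogger(__name__)

SIDECAR_FIELDS = ("fs_hz", "n_channels", "uv_per_count", "positions_mm", "channel_ids")


class CorruptFileError(RuntimeError):
    """Binary size inconsistent with the sidecar channel count."""


class SchemaError(KeyError):
    """A required sidecar field is missing."""


@dataclass
class Recording:
    """Multichannel extracellular recording.

    Attributes
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Voltages in µV.
    fs_hz : float
        Sampling rate.
    positions_mm : ndarray
        Distance of each channel from the dorsal-most electrode (mm,
        strictly increasing ventrally).
    channel_ids : list of str
        Channel labels.
    meta : dict
        Free-form provenance.
    """

    samples: np.ndarray
    fs_hz: float
    positions_mm: np.ndarray
    channel_ids: list = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels x time)")
        self.positions_mm = np.asarray(self.positions_mm, dtype=float)
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if len(self.positions_mm) != self.samples.shape[0]:
            raise ValueError("positions_mm length must equal channel count")
        if len(self.positions_mm) > 1 and np.any(np.diff(self.positions_mm) <= 0):
            raise ValueError("positions_mm must be strictly increasing")
        if self.channel_ids is None:
            self.channel_ids = [f"ch{i}" for i in range(self.samples.shape[0])]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs_hz

    def copy(self) -> "Recording":
        return Recording(
            samples=self.samples.copy(),
            fs_hz=self.fs_hz,
            positions_mm=self.positions_mm.copy(),
            channel_ids=list(self.channel_ids),
            meta=dict(self.meta),
        )


@dataclass
class EpochSet:
    """Sorted, non-overlapping half-open [start_s, end_s) intervals."""

    intervals: list

    def __post_init__(self):
        iv = [(float(a), float(b)) for a, b in self.intervals]
        iv.sort()
        for a, b in iv:
            if a >= b:
                raise ValueError(f"empty or inverted interval [{a}, {b})")
        for (a0, b0), (a1, b1) in zip(iv, iv[1:]):
            if a1 < b0:
                raise ValueError("overlapping intervals")
        self.intervals = iv

    def __len__(self):
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    @property
    def total_s(self) -> float:
        return sum(b - a for a, b in self.intervals)

    def contains(self, t: np.ndarray) -> np.ndarray:
        """Boolean membership of times ``t`` in any interval."""
        t = np.asarray(t, dtype=float)
        out = np.zeros(t.shape, dtype=bool)
        for a, b in self.intervals:
            out |= (t >= a) & (t < b)
        return out

    def sample_mask(self, n_samples: int, fs_hz: float) -> np.ndarray:
        mask = np.zeros(n_samples, dtype=bool)
        for a, b in self.intervals:
            i0 = max(0, int(np.ceil(a * fs_hz)))
            i1 = min(n_samples, int(np.ceil(b * fs_hz)))
            mask[i0:i1] = True
        return mask

    def to_csv(self, path):
        pd.DataFrame(self.intervals, columns=["start_s", "end_s"]).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "EpochSet":
        df = pd.read_csv(path)
        return cls(list(zip(df["start_s"], df["end_s"])))


def write_recording(recording: Recording, path, uv_per_count: float = 0.195) -> None:
    """Write ``lfp.dat`` + ``lfp.json`` under directory ``path``.

    Voltages are quantized by ``uv_per_count``; values outside the int16
    range are clipped to ±32767 counts with a warning.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    counts = np.round(recording.samples / uv_per_count)
    n_clip = int(np.sum((counts > 32767) | (counts < -32768)))
    if n_clip:
        warnings.warn(
            f"{n_clip} samples exceed the int16 range and were clipped",
            RuntimeWarning,
        )
        log.warning("write_recording: %d samples saturated", n_clip)
    counts = np.clip(counts, -32768, 32767).astype("<i2")
    # channel-fastest interleave: sample-major on disk
    counts.T.tofile(path / "lfp.dat")
    sidecar = {
        "fs_hz": recording.fs_hz,
        "n_channels": recording.n_channels,
        "uv_per_count": uv_per_count,
        "positions_mm": list(map(float, recording.positions_mm)),
        "channel_ids": list(recording.channel_ids),
        "meta": recording.meta,
    }
    (path / "lfp.json").write_text(json.dumps(sidecar, indent=1, default=str))


def read_recording(path) -> Recording:
    """Read a recording written by :func:`write_recording`."""
    path = Path(path)
    sidecar_path = path / "lfp.json"
    if not sidecar_path.exists():
        raise SchemaError(f"missing sidecar file {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    for key in SIDECAR_FIELDS:
        if key not in sidecar:
            raise SchemaError(f"sidecar missing required field '{key}'")
    n_channels = int(sidecar["n_channels"])
    raw = np.fromfile(path / "lfp.dat", dtype="<i2")
    if raw.size % n_channels:
        raise CorruptFileError(
            f"lfp.dat holds {raw.size} values, not divisible by "
            f"n_channels={n_channels}"
        )
    samples = raw.reshape(-1, n_channels).T.astype(float) * sidecar["uv_per_count"]
    return Recording(
        samples=samples,
        fs_hz=float(sidecar["fs_hz"]),
        positions_mm=np.asarray(sidecar["positions_mm"], dtype=float),
        channel_ids=list(sidecar["channel_ids"]),
        meta=sidecar.get("meta", {}),
    )


def decimate(recording: Recording, target_fs: float) -> Recording:
    """Anti-alias low-pass and subsample to ``target_fs``.

    Zero-phase 8th-order Butterworth at 0.4×target_fs, then take every
    k-th sample. ``fs_hz`` must be an integer multiple of ``target_fs``.
    """
    factor = recording.fs_hz / target_fs
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"fs {recording.fs_hz} not an integer multiple of {target_fs}"
        )
    factor = int(round(factor))
    if factor == 1:
        return recording.copy()
    sos = signal.butter(8, 0.4 * target_fs, btype="low", fs=recording.fs_hz, output="sos")
    filtered = signal.sosfiltfilt(sos, recording.samples, axis=1)
    out = recording.copy()
    out.samples = filtered[:, ::factor]
    out.fs_hz = float(target_fs)
    out.meta = {**recording.meta, "decimated_from_hz": recording.fs_hz}
    return out
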
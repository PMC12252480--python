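"""Readers for the three recording formats and window slicing.

Recordings arrive either as CSV serial-plotter logs (timestamp in ms plus one
column per channel), as mono WAV audio from a digital stethoscope, or as MAT
containers holding named ECG/PCG vectors.  Everything is normalised into
:class:`SampledSignal` / :class:`RecordingPair` so the downstream segmentation
never cares where the samples came from.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.io import loadmat, wavfile

__all__ = [
    "SampledSignal",
    "RecordingPair",
    "SourceFormat",
    "read_csv_recording",
    "read_wav",
    "read_mat_recording",
    "iter_windows",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SampledSignal:
    """A uniformly sampled 1-D waveform.

    Parameters
    ----------
    samples:
        Amplitude values (arbitrary units or volts).
    fs:
        Sampling rate in Hz (> 0).
    t0:
        Absolute time of the first sample in seconds.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if samples.ndim != 1:
            raise ValueError("samples must be 1-D")
        if samples.size < 2:
            raise ValueError("a signal needs at least 2 samples")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples contain non-finite values")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record length in seconds (n / fs)."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Absolute time axis: t0 + i / fs for each sample i."""
        return self.t0 + np.arange(self.samples.size) / self.fs

    def index_of(self, t: float) -> int:
        """Nearest sample index for an absolute time, clipped to range."""
        i = int(round((t - self.t0) * self.fs))
        return min(max(i, 0), self.samples.size - 1)

    def scaled(self, factor: float) -> "SampledSignal":
        return replace(self, samples=self.samples * factor)


class SourceFormat(str, Enum):
    CSV = "csv"
    WAV = "wav"
    MAT = "mat"
    SYNTH = "synth"


@dataclass(frozen=True)
class RecordingPair:
    """A synchronised PCG + ECG pair sharing one sampling rate."""

    pcg: SampledSignal
    ecg: SampledSignal
    source_format: SourceFormat = SourceFormat.SYNTH
    label: str = ""

    def __post_init__(self) -> None:
        if self.pcg.fs != self.ecg.fs:
            raise ValueError(
                f"channel sampling rates differ: pcg {self.pcg.fs} Hz vs "
                f"ecg {self.ecg.fs} Hz"
            )
        if len(self.pcg) != len(self.ecg):
            raise ValueError("pcg and ecg must have equal length after alignment")

    @property
    def fs(self) -> float:
        return self.pcg.fs


def read_csv_recording(
    path: str | Path,
    pcg_col: int = 1,
    ecg_col: int = 2,
    time_col: int = 0,
    time_unit: str = "ms",
    fs_override: float | None = None,
    label: str | None = None,
) -> RecordingPair:
    """Read a serial-plotter CSV log into a :class:`RecordingPair`.

    The first (configurable) column is a timestamp printed by the firmware's
    millisecond clock; the sampling rate is inferred as ``1 / median(diff)``
    of the timestamps unless ``fs_override`` is given.  Column indices are
    configuration because serial logs are device-session specific.

    Raises
    ------
    ValueError
        If the file has fewer than 2 rows, fewer than the required columns,
        or timestamps that decrease.
    """
    path = Path(path)
    df = pd.read_csv(path, header=None, comment="#", skip_blank_lines=True)
    # Tolerate an optional non-numeric header row.
    if df.shape[0] and not np.issubdtype(np.asarray(df.iloc[0]).dtype, np.number):
        try:
            df.iloc[0].astype(float)
        except (TypeError, ValueError):
            df = df.iloc[1:].reset_index(drop=True)
    if df.shape[0] < 2:
        raise ValueError(f"{path}: need at least 2 rows, got {df.shape[0]}")
    needed = max(time_col, pcg_col, ecg_col) + 1
    if df.shape[1] < needed:
        raise ValueError(
            f"{path}: need at least {needed} columns, found {df.shape[1]}"
        )
    t = df.iloc[:, time_col].astype(float).to_numpy()
    scale = 1e-3 if time_unit == "ms" else 1.0
    t = t * scale
    dt = np.diff(t)
    if np.any(dt < 0):
        bad = int(np.argmax(dt < 0)) + 1
        raise ValueError(
            f"{path}: timestamps decrease at row {bad} "
            f"({t[bad - 1]:g} -> {t[bad]:g} s); cannot infer sampling rate"
        )
    if fs_override is not None:
        fs = float(fs_override)
    else:
        med = float(np.median(dt))
        if med <= 0:
            raise ValueError(f"{path}: median timestamp step is not positive")
        fs = 1.0 / med
    pcg = SampledSignal(df.iloc[:, pcg_col].astype(float).to_numpy(), fs, t0=t[0])
    ecg = SampledSignal(df.iloc[:, ecg_col].astype(float).to_numpy(), fs, t0=t[0])
    return RecordingPair(pcg, ecg, SourceFormat.CSV, label or path.name)


def read_wav(path: str | Path) -> SampledSignal:
    """Read mono (or first-channel) WAV audio, scaled into [-1, 1].

    Integer PCM encodings are divided by their full scale; float files are
    passed through unchanged.
    """
    path = Path(path)
    fs, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[:, 0]
    if data.dtype == np.int16:
        samples = data / 32768.0
    elif data.dtype == np.int32:
        samples = data / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(float) - 128.0) / 128.0
    else:
        samples = data.astype(float)
    return SampledSignal(samples, float(fs), t0=0.0)


def _load_mat_vars(path: Path) -> dict[str, np.ndarray]:
    try:
        raw = loadmat(path)
        return {
            k: np.asarray(v).squeeze()
            for k, v in raw.items()
            if not k.startswith("__") and np.asarray(v).size > 1
        }
    except NotImplementedError:
        # MAT v7.3 files are HDF5 underneath.
        import h5py

        out: dict[str, np.ndarray] = {}
        with h5py.File(path, "r") as f:
            for k in f:
                node = f[k]
                if isinstance(node, h5py.Dataset):
                    arr = np.asarray(node[()]).squeeze()
                    if arr.size > 1:
                        out[k] = arr
        return out


def read_mat_recording(
    path: str | Path,
    ecg_key: str,
    pcg_key: str,
    fs: float = 20_000.0,
    label: str | None = None,
) -> RecordingPair:
    """Read named ECG/PCG vectors from a MAT container (v5 or v7.3).

    ``fs`` defaults to 20 kHz, the rate the supported open dataset was
    recorded at; override it for other containers.
    """
    path = Path(path)
    variables = _load_mat_vars(path)
    for key in (ecg_key, pcg_key):
        if key not in variables:
            raise KeyError(
                f"{path}: variable {key!r} not found; available: "
                f"{sorted(variables)}"
            )
    ecg = np.ravel(variables[ecg_key]).astype(float)
    pcg = np.ravel(variables[pcg_key]).astype(float)
    n = min(ecg.size, pcg.size)
    if ecg.size != pcg.size:
        log.warning(
            "%s: channel lengths differ (%d vs %d); truncating to %d",
            path, ecg.size, pcg.size, n,
        )
    return RecordingPair(
        SampledSignal(pcg[:n], fs, 0.0),
        SampledSignal(ecg[:n], fs, 0.0),
        SourceFormat.MAT,
        label or path.name,
    )


def iter_windows(
    sig: SampledSignal, window_s: float = 10.0
) -> Iterator[SampledSignal]:
    """Yield consecutive non-overlapping windows of ``window_s`` seconds.

    The trailing remainder shorter than one window is dropped; each window's
    ``t0`` is its absolute start time.  A signal shorter than one window
    yields nothing.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    n_win = int(round(window_s * sig.fs))
    if n_win < 2:
        raise ValueError("window too short for this sampling rate")
    for k in range(len(sig) // n_win):
        start = k * n_win
        yield SampledSignal(
            sig.samples[start : start + n_win],
            sig.fs,
            t0=sig.t0 + start / sig.fs,
        )
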
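"""QRS delineation on the conditioned ECG: R, Q and S wave peaks.

R peaks are local maxima above half the maximum ECG amplitude.  Q and S are
searched in fixed 250 ms windows before/after each R peak as local maxima of
the negated ECG above an adaptive threshold of ``0.2 * max(-ecg)``; ties are
broken toward R for Q (the Q trough immediately precedes R) and toward the
earliest candidate for S.  All thresholds are relative, so fiducial times are
invariant to positive rescaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .signal_io import SampledSignal

__all__ = [
    "QrsDetectorParams",
    "EcgFiducials",
    "detect_r_peaks",
    "detect_q_peaks",
    "detect_s_waves",
    "segment_ecg",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class QrsDetectorParams:
    """Tunables of the QRS delineator (defaults are the algorithm's constants)."""

    r_frac: float = 0.5
    qs_frac: float = 0.2
    search_half_window_s: float = 0.250
    s_min_dist_cap_s: float = 0.05
    s_min_dist_range_frac: float = 0.9
    #: "adaptive" uses qs_frac * max(-ecg) for Q; "fixed" uses q_fixed_height.
    q_height_mode: str = "adaptive"
    q_fixed_height: float = 0.1
    #: Optional minimum R-R separation guarding against notched R peaks.
    r_min_separation_s: float | None = None

    def __post_init__(self) -> None:
        for name in ("r_frac", "qs_frac"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.search_half_window_s <= 0:
            raise ValueError("search_half_window_s must be positive")
        if self.q_height_mode not in ("adaptive", "fixed"):
            raise ValueError(f"unknown q_height_mode {self.q_height_mode!r}")


@dataclass
class EcgFiducials:
    """Per-beat ECG landmarks; missing Q/S are NaN."""

    q_t: np.ndarray
    r_t: np.ndarray
    s_t: np.ndarray
    window_id: int = 0

    def __post_init__(self) -> None:
        self.q_t = np.asarray(self.q_t, dtype=float)
        self.r_t = np.asarray(self.r_t, dtype=float)
        self.s_t = np.asarray(self.s_t, dtype=float)
        if not (self.q_t.size == self.r_t.size == self.s_t.size):
            raise ValueError("fiducial arrays must have equal length")

    @property
    def n_beats(self) -> int:
        return self.r_t.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "window_id": self.window_id,
                "beat": np.arange(self.n_beats),
                "q_t": self.q_t,
                "r_t": self.r_t,
                "s_t": self.s_t,
            }
        )


def detect_r_peaks(
    ecg: SampledSignal, params: QrsDetectorParams = QrsDetectorParams()
) -> np.ndarray:
    """R peak times: local maxima above ``r_frac * max(ecg)``."""
    x = ecg.samples
    if x.max() <= 0 or np.ptp(x) == 0:
        raise ValueError("degenerate ECG: no positive deflection")
    distance = None
    if params.r_min_separation_s is not None:
        distance = max(1, int(round(params.r_min_separation_s * ecg.fs)))
    locs, _ = find_peaks(x, height=params.r_frac * x.max(), distance=distance)
    return ecg.t0 + locs / ecg.fs


def _qs_height(ecg: SampledSignal, params: QrsDetectorParams) -> float:
    if params.q_height_mode == "fixed":
        return params.q_fixed_height
    return params.qs_frac * float((-ecg.samples).max())


def detect_q_peaks(
    ecg: SampledSignal,
    r_t: np.ndarray,
    params: QrsDetectorParams = QrsDetectorParams(),
) -> np.ndarray:
    """Q trough per beat: negated-ECG maxima in [r - 250 ms, r], closest to R."""
    x = ecg.samples
    fs = ecg.fs
    height = _qs_height(ecg, params)
    half = int(round(params.search_half_window_s * fs))
    out = np.full(len(np.atleast_1d(r_t)), np.nan)
    for i, r in enumerate(np.atleast_1d(r_t)):
        r_idx = ecg.index_of(r)
        lo = max(r_idx - half, 0)
        if r_idx - lo < 3:
            continue
        locs, _ = find_peaks(-x[lo : r_idx + 1], height=height)
        if locs.size == 0:
            continue
        out[i] = ecg.t0 + (lo + locs[-1]) / fs  # rightmost = closest to R
    return out


def detect_s_waves(
    ecg: SampledSignal,
    r_t: np.ndarray,
    params: QrsDetectorParams = QrsDetectorParams(),
) -> np.ndarray:
    """S trough per beat: earliest negated-ECG maximum in [r, r + 250 ms].

    Candidate troughs must clear the adaptive height and be separated by at
    least ``min(s_min_dist_cap_s, s_min_dist_range_frac * window span)``.
    """
    x = ecg.samples
    fs = ecg.fs
    height = _qs_height(ecg, params)
    half = int(round(params.search_half_window_s * fs))
    out = np.full(len(np.atleast_1d(r_t)), np.nan)
    for i, r in enumerate(np.atleast_1d(r_t)):
        r_idx = ecg.index_of(r)
        hi = min(r_idx + half, len(x) - 1)
        if hi - r_idx < 3:
            continue
        span = (hi - r_idx) / fs
        min_dist_s = min(params.s_min_dist_cap_s,
                         params.s_min_dist_range_frac * span)
        distance = max(1, int(round(min_dist_s * fs)))
        locs, _ = find_peaks(-x[r_idx : hi + 1], height=height,
                             distance=distance)
        if locs.size == 0:
            continue
        out[i] = ecg.t0 + (r_idx + locs[0]) / fs  # earliest after R
    return out


def segment_ecg(
    ecg_conditioned: SampledSignal,
    params: QrsDetectorParams = QrsDetectorParams(),
    window_id: int = 0,
) -> EcgFiducials:
    """Full per-window QRS delineation."""
    r = detect_r_peaks(ecg_conditioned, params)
    q = detect_q_peaks(ecg_conditioned, r, params)
    s = detect_s_waves(ecg_conditioned, r, params)
    return EcgFiducials(q, r, s, window_id)
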
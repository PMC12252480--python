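"""Adaptive segmentation of the phonocardiogram: S1 peaks, S2 peaks, S1 onsets.

All thresholds are relative to the signal itself, so detections are invariant
to positive rescaling of the PCG:

* S1 candidates are centres of contiguous runs where the squared PCG exceeds
  ``a_frac * max(pcg**2)``; candidates are then gated by a signed amplitude
  threshold ``b_frac * mean(pcg at candidates)`` and a 425 ms refractory rule.
* An amplitude-consistency filter accepts a beat only if its S1 amplitude is
  within 40 % of a running average of previously accepted S1 amplitudes.
* S2 is searched between consecutive S1 peaks among local maxima of the
  squared PCG whose delay after S1 lies strictly within 125-500 ms; the
  reported S2 time is the mean of surviving candidate times.
* The S1 onset is found on the 40 Hz low-passed PCG by locating prominent
  troughs and walking backward until the signal stops decreasing, then
  validating the onset against a known S1 within 50 ms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .signal_io import SampledSignal

__all__ = [
    "S1DetectorParams",
    "OnsetParams",
    "PcgFiducials",
    "detect_s1_peaks",
    "consistency_filter",
    "detect_s2_peaks",
    "detect_s1_onsets",
    "segment_pcg",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class S1DetectorParams:
    """Tunables of the S1 detector (defaults are the algorithm's constants)."""

    a_frac: float = 0.1          # squared-amplitude threshold fraction
    b_frac: float = 0.5          # signed amplitude gate fraction
    refractory_s: float = 0.425  # minimum S1-to-S1 spacing
    consistency_tol: float = 0.40
    running_avg_len: int = 5
    refractory_mode: str = "greedy"  # "greedy" | "vectorized"

    def __post_init__(self) -> None:
        for name in ("a_frac", "b_frac", "consistency_tol"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.refractory_s <= 0:
            raise ValueError("refractory_s must be positive")
        if self.running_avg_len < 1:
            raise ValueError("running_avg_len must be >= 1")
        if self.refractory_mode not in ("greedy", "vectorized"):
            raise ValueError(f"unknown refractory_mode {self.refractory_mode!r}")


@dataclass(frozen=True)
class OnsetParams:
    """Tunables of the S1 onset search on the low-passed PCG."""

    height_frac: float = 0.2        # trough height fraction of max(-pcg)
    min_peak_distance_s: float = 0.2
    validation_tol_s: float = 0.05  # onset must be this close to a known S1


@dataclass(frozen=True)
class S2Params:
    """Tunables of the S2 search between consecutive S1 peaks."""

    min_delay_s: float = 0.125   # strict lower bound on S2 - S1
    max_delay_s: float = 0.5     # strict upper bound
    mode: str = "mean"           # "mean" | "max"
    min_height_frac: float = 0.1  # relative gate on squared-signal maxima

    def __post_init__(self) -> None:
        if self.mode not in ("mean", "max"):
            raise ValueError(f"unknown S2 mode {self.mode!r}")


@dataclass
class PcgFiducials:
    """Per-beat PCG landmarks; missing S2/onsets are NaN."""

    s1_peak_t: np.ndarray
    s1_onset_t: np.ndarray
    s2_peak_t: np.ndarray
    window_id: int = 0
    edge: np.ndarray = field(default=None)  # beats too close to a window edge

    def __post_init__(self) -> None:
        self.s1_peak_t = np.asarray(self.s1_peak_t, dtype=float)
        self.s1_onset_t = np.asarray(self.s1_onset_t, dtype=float)
        self.s2_peak_t = np.asarray(self.s2_peak_t, dtype=float)
        if self.edge is None:
            self.edge = np.zeros(self.s1_peak_t.size, dtype=bool)
        self.edge = np.asarray(self.edge, dtype=bool)
        n = self.s1_peak_t.size
        if not (self.s1_onset_t.size == self.s2_peak_t.size == self.edge.size == n):
            raise ValueError("fiducial arrays must have equal length")

    @property
    def n_beats(self) -> int:
        return self.s1_peak_t.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "window_id": self.window_id,
                "beat": np.arange(self.n_beats),
                "s1_onset_t": self.s1_onset_t,
                "s1_peak_t": self.s1_peak_t,
                "s2_peak_t": self.s2_peak_t,
                "edge": self.edge,
            }
        )


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive (start, stop) index pairs of contiguous True runs."""
    if not mask.any():
        return []
    padded = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1) - 1
    return list(zip(starts.tolist(), stops.tolist()))


def detect_s1_peaks(
    pcg: SampledSignal, params: S1DetectorParams = S1DetectorParams()
) -> np.ndarray:
    """Detect S1 peak times (seconds, absolute) in a conditioned PCG window.

    Steps: squared-amplitude thresholding, run-centre extraction, signed
    amplitude gating, then the refractory rule.  Raises ``ValueError`` on a
    flat (all-zero) signal.
    """
    x = pcg.samples
    sq = x * x
    peak = sq.max()
    if peak <= 0:
        raise ValueError("degenerate signal: max(pcg^2) is zero")
    mask = sq >= params.a_frac * peak
    centers = np.array([(a + b) // 2 for a, b in _runs(mask)], dtype=int)
    if centers.size == 0:
        log.warning("no S1 candidates above the squared-amplitude threshold")
        return np.empty(0)
    vals = x[centers]
    b_th = params.b_frac * vals.mean()
    centers = centers[vals >= b_th]
    if centers.size == 0:
        log.warning("no S1 candidates survived the amplitude gate")
        return np.empty(0)
    times = pcg.t0 + centers / pcg.fs

    if params.refractory_mode == "greedy":
        kept: list[float] = []
        for t in times:
            if not kept or t - kept[-1] >= params.refractory_s:
                kept.append(float(t))
        return np.array(kept)
    # "vectorized": single diff pass against the immediate predecessor in the
    # candidate list, which can compare against an already-discarded peak.
    keep = np.concatenate(([True], np.diff(times) >= params.refractory_s))
    return times[keep]


def consistency_filter(
    s1_t: np.ndarray,
    pcg: SampledSignal,
    params: S1DetectorParams = S1DetectorParams(),
) -> np.ndarray:
    """Keep S1 detections whose amplitude tracks a running average.

    A detection is accepted iff ``|amp - ref| <= consistency_tol * ref``
    (closed bound) where ``ref`` is the running mean of the last
    ``running_avg_len`` accepted S1 amplitudes, seeded for the first beat with
    the median candidate amplitude.
    """
    s1_t = np.asarray(s1_t, dtype=float)
    if s1_t.size == 0:
        return s1_t
    amps = pcg.samples[[pcg.index_of(t) for t in s1_t]]
    ref = float(np.median(amps))
    accepted_t: list[float] = []
    accepted_a: list[float] = []
    for t, a in zip(s1_t, amps):
        if abs(a - ref) <= params.consistency_tol * ref:
            accepted_t.append(float(t))
            accepted_a.append(float(a))
            ref = float(np.mean(accepted_a[-params.running_avg_len:]))
    return np.array(accepted_t)


def detect_s2_peaks(
    pcg: SampledSignal,
    s1_t: np.ndarray,
    params: S2Params = S2Params(),
) -> np.ndarray:
    """Find one S2 time per beat (NaN where no valid candidate exists).

    For beat ``j`` the squared PCG is searched in ``(s1[j], s1[j+1]]`` (last
    beat: to the end of the window) for local maxima whose delay after S1 lies
    strictly within the 125-500 ms systolic window; the reported time is the
    mean of surviving candidate times (``mode="max"``: the largest candidate).
    Maxima below ``min_height_frac`` of the search range's squared maximum are
    ignored so that broadband noise wiggles do not enter the average; set it
    to 0 to consider every local maximum.
    """
    s1_t = np.asarray(s1_t, dtype=float)
    if s1_t.size == 0:
        raise ValueError("s1_t must be non-empty")
    x = pcg.samples
    sq = x * x
    fs = pcg.fs
    out = np.full(s1_t.size, np.nan)
    for j, t1 in enumerate(s1_t):
        start = pcg.index_of(t1)
        stop = pcg.index_of(s1_t[j + 1]) if j + 1 < s1_t.size else len(x) - 1
        if stop - start < 3:
            continue
        seg = sq[start : stop + 1]
        height = params.min_height_frac * seg.max() if params.min_height_frac else None
        locs, props = find_peaks(seg, height=height)
        if locs.size == 0:
            continue
        delays = locs / fs
        ok = (delays > params.min_delay_s) & (delays < params.max_delay_s)
        if not ok.any():
            continue
        if params.mode == "mean":
            out[j] = t1 + delays[ok].mean()
        else:
            heights = seg[locs[ok]]
            out[j] = t1 + delays[ok][int(np.argmax(heights))]
    return out


def detect_s1_onsets(
    pcg_lp: SampledSignal,
    s1_t: np.ndarray,
    params: OnsetParams = OnsetParams(),
) -> np.ndarray:
    """Locate one S1 onset per beat on the 40 Hz low-passed PCG (NaN if none).

    Prominent troughs (inverted-signal peaks above ``0.2 * max(-pcg)``, at
    least 200 ms apart) seed a backward walk that stops at the first
    non-decreasing step; a candidate onset survives only if it lies within
    50 ms of some S1 peak and does not come after it.  Each beat takes its
    earliest surviving candidate.
    """
    s1_t = np.asarray(s1_t, dtype=float)
    x = pcg_lp.samples
    out = np.full(s1_t.size, np.nan)
    inv = -x
    max_inv = inv.max()
    if max_inv <= 0:
        log.warning("no negative deflections: cannot locate S1 onsets")
        return out
    locs, _ = find_peaks(
        inv,
        height=params.height_frac * max_inv,
        distance=max(1, int(round(params.min_peak_distance_s * pcg_lp.fs))),
    )
    half_sample = 0.5 / pcg_lp.fs
    for loc in locs:
        idx = int(loc)
        while idx > 0 and x[idx] < x[idx - 1]:
            idx -= 1
        t_onset = pcg_lp.t0 + idx / pcg_lp.fs
        if s1_t.size == 0:
            continue
        j = int(np.argmin(np.abs(s1_t - t_onset)))
        if abs(s1_t[j] - t_onset) > params.validation_tol_s:
            continue  # not close to any known S1: reject as false positive
        if t_onset > s1_t[j] + half_sample:
            continue  # onset cannot follow its S1 peak
        if np.isnan(out[j]) or t_onset < out[j]:
            out[j] = t_onset
    return out


def segment_pcg(
    pcg_conditioned: SampledSignal,
    pcg_lowpassed: SampledSignal,
    s1_params: S1DetectorParams = S1DetectorParams(),
    s2_params: S2Params = S2Params(),
    onset_params: OnsetParams = OnsetParams(),
    window_id: int = 0,
    edge_margin_s: float = 0.1,
) -> PcgFiducials:
    """Full per-window PCG segmentation: S1 peaks -> consistency -> S2, onsets.

    Beats whose S1 lies within ``edge_margin_s`` of either window edge are
    flagged so interval statistics can exclude them.
    """
    s1 = detect_s1_peaks(pcg_conditioned, s1_params)
    s1 = consistency_filter(s1, pcg_conditioned, s1_params)
    if s1.size == 0:
        return PcgFiducials(np.empty(0), np.empty(0), np.empty(0), window_id)
    s2 = detect_s2_peaks(pcg_conditioned, s1, s2_params)
    onsets = detect_s1_onsets(pcg_lowpassed, s1, onset_params)
    t_start = pcg_conditioned.t0
    t_end = t_start + pcg_conditioned.duration
    edge = (s1 - t_start < edge_margin_s) | (t_end - s1 < edge_margin_s)
    return PcgFiducials(s1, onsets, s2, window_id, edge)
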
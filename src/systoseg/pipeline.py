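"""End-to-end processing: windows -> fiducials -> intervals -> summary."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from . import ecg_seg, intervals, pcg_seg, preprocess
from .config import PipelineConfig
from .signal_io import RecordingPair, iter_windows

__all__ = ["segment_recording", "extract_intervals", "WindowLog"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowLog:
    """Per-window quality-control counters."""

    window_id: int
    t_start: float
    n_s1: int
    n_r: int
    n_missing_s2: int
    n_missing_onset: int
    n_missing_q: int


def segment_recording(
    pair: RecordingPair, config: PipelineConfig = PipelineConfig()
) -> tuple[pd.DataFrame, pd.DataFrame, list[WindowLog]]:
    """Segment both channels over consecutive non-overlapping windows.

    Returns tidy PCG and ECG fiducial tables (absolute times, one row per
    beat) and a per-window QC log.  Windows where a detector degenerates
    (flat signal, no beats) are logged and skipped.
    """
    pcg_rows: list[pd.DataFrame] = []
    ecg_rows: list[pd.DataFrame] = []
    logs: list[WindowLog] = []
    windows = zip(
        iter_windows(pair.pcg, config.window_s),
        iter_windows(pair.ecg, config.window_s),
    )
    for wid, (pcg_w, ecg_w) in enumerate(windows):
        try:
            pcg_c = preprocess.condition_pcg(pcg_w)
            pcg_lp = preprocess.lowpass_for_onset(pcg_w, config.onset_lowpass)
            ecg_c = preprocess.condition_ecg(ecg_w, config.ecg_highpass)
            pfid = pcg_seg.segment_pcg(
                pcg_c, pcg_lp,
                s1_params=config.s1, s2_params=config.s2,
                onset_params=config.onset,
                window_id=wid, edge_margin_s=config.edge_margin_s,
            )
            efid = ecg_seg.segment_ecg(ecg_c, config.qrs, window_id=wid)
        except ValueError as exc:
            log.warning("window %d skipped: %s", wid, exc)
            continue
        pdf, edf = pfid.to_frame(), efid.to_frame()
        pcg_rows.append(pdf)
        ecg_rows.append(edf)
        logs.append(
            WindowLog(
                window_id=wid,
                t_start=pcg_w.t0,
                n_s1=pfid.n_beats,
                n_r=efid.n_beats,
                n_missing_s2=int(pdf["s2_peak_t"].isna().sum()),
                n_missing_onset=int(pdf["s1_onset_t"].isna().sum()),
                n_missing_q=int(edf["q_t"].isna().sum()),
            )
        )
    empty_p = pd.DataFrame(
        columns=["window_id", "beat", "s1_onset_t", "s1_peak_t",
                 "s2_peak_t", "edge"])
    empty_e = pd.DataFrame(columns=["window_id", "beat", "q_t", "r_t", "s_t"])
    pcg_df = pd.concat(pcg_rows, ignore_index=True) if pcg_rows else empty_p
    ecg_df = pd.concat(ecg_rows, ignore_index=True) if ecg_rows else empty_e
    return pcg_df, ecg_df, logs


def extract_intervals(
    pcg_df: pd.DataFrame,
    ecg_df: pd.DataFrame,
    config: PipelineConfig = PipelineConfig(),
) -> tuple[pd.DataFrame, intervals.IntervalSummary, intervals.ClinicalFlags]:
    """Pair beats window by window and compute intervals + summary + flags."""
    beat_tables = []
    wids = sorted(set(pcg_df.get("window_id", pd.Series(dtype=int)).unique())
                  & set(ecg_df.get("window_id", pd.Series(dtype=int)).unique()))
    for wid in wids:
        paired = intervals.pair_beats(
            pcg_df[pcg_df["window_id"] == wid],
            ecg_df[ecg_df["window_id"] == wid],
            max_lag_s=config.pairing_max_lag_s,
        )
        if not paired.empty:
            beat_tables.append(intervals.compute_intervals(paired))
    if beat_tables:
        beats = pd.concat(beat_tables, ignore_index=True)
        beats = intervals.normalize_intervals(beats)
    else:
        log.warning("no paired beats in any window")
        beats = intervals.normalize_intervals(
            intervals.compute_intervals(intervals.pair_beats(
                pd.DataFrame(columns=["s1_onset_t", "s1_peak_t",
                                      "s2_peak_t", "edge"]),
                pd.DataFrame(columns=["q_t", "r_t", "s_t"]),
            ))
        )
    summary = intervals.summarize(beats)
    flags = intervals.clinical_flags(summary, beats)
    return beats, summary, flags
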
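"""Beat pairing and systolic time interval computation.

The systolic times are defined from paired ECG/PCG fiducials of one cardiac
cycle:

* ``EMAT = S1_onset - Q`` (electromechanical activation time)
* ``PEP  = S1_peak  - Q`` (pre-ejection period, operational definition)
* ``LVET = S2_peak  - S1_peak`` (left-ventricular ejection time)
* ``LVST = S2_peak  - S1_onset`` (left-ventricular systolic time)
* ``S1R  = S1_onset - R``

all in milliseconds, so the identity ``LVST - LVET = PEP - EMAT`` holds
exactly whenever all four are present.  Each interval can be normalised by
the beat's RR interval (fractions), and window means are checked against
literature thresholds for left-ventricular dysfunction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .ecg_seg import EcgFiducials
from .pcg_seg import PcgFiducials

__all__ = [
    "INTERVAL_COLUMNS",
    "IntervalSummary",
    "ClinicalFlags",
    "pair_beats",
    "compute_intervals",
    "normalize_intervals",
    "summarize",
    "clinical_flags",
]

log = logging.getLogger(__name__)

INTERVAL_COLUMNS = ("emat_ms", "pep_ms", "lvet_ms", "lvst_ms", "s1r_ms")

#: Typical physiological ranges (ms) for a resting adult, used as sanity
#: bounds in reports.
TYPICAL_RANGES_MS = {
    "emat_ms": (50.0, 120.0),
    "pep_ms": (50.0, 120.0),
    "lvet_ms": (150.0, 350.0),
    "lvst_ms": (150.0, 350.0),
}


@dataclass(frozen=True)
class IntervalSummary:
    """Per-interval summary statistics over the analysed beats."""

    stats: dict  # interval name -> {mean, sd, median, iqr, n}

    def __getitem__(self, key: str) -> dict:
        return self.stats[key]

    def mean(self, key: str) -> float:
        return self.stats.get(key, {}).get("mean", float("nan"))

    def to_dict(self) -> dict:
        return {k: dict(v) for k, v in self.stats.items()}


@dataclass(frozen=True)
class ClinicalFlags:
    """Tri-state screening flags computed on window-mean intervals.

    ``None`` means the inputs needed for that flag were missing.  Thresholds
    come from the clinical literature on left-ventricular dysfunction:
    EMAT% > 12.1 %, EMAT >= 104 ms, %EMAT > 13.8 %, EMAT/LVST >= 0.40.
    """

    emat_pct_gt_12_1: bool | None
    emat_ge_104ms: bool | None
    emat_pct_gt_13_8: bool | None
    emat_over_lvst_ge_0_40: bool | None

    def to_dict(self) -> dict:
        return asdict(self)


def pair_beats(
    pcg_fid: PcgFiducials | pd.DataFrame,
    ecg_fid: EcgFiducials | pd.DataFrame,
    max_lag_s: float = 0.250,
) -> pd.DataFrame:
    """Align PCG and ECG fiducials beat-by-beat.

    Each Q is paired with the earliest unused PCG beat whose S1 anchor (onset
    when present, else peak) follows it within ``max_lag_s``.  Unpaired
    fiducials on either side are dropped.  RR is computed from consecutive
    paired R peaks (the last beat's RR is NaN).

    Noise can split one QRS complex into several R detections that all
    resolve to the same Q; such duplicates are collapsed to the row with the
    median R time before pairing, so one cardiac cycle yields one beat.
    """
    pdf = pcg_fid.to_frame() if isinstance(pcg_fid, PcgFiducials) else pcg_fid.copy()
    edf = ecg_fid.to_frame() if isinstance(ecg_fid, EcgFiducials) else ecg_fid.copy()
    pdf = pdf.sort_values("s1_peak_t").reset_index(drop=True)
    edf = edf.sort_values("r_t").reset_index(drop=True)
    valid_q = edf["q_t"].notna()
    if valid_q.any() and edf.loc[valid_q, "q_t"].duplicated().any():
        groups = [g.sort_values("r_t").iloc[len(g) // 2]
                  for _, g in edf[valid_q].groupby("q_t", sort=True)]
        edf = pd.DataFrame(groups).sort_values("r_t").reset_index(drop=True)
    if "edge" not in pdf.columns:
        pdf["edge"] = False

    anchors = np.where(
        np.isnan(pdf["s1_onset_t"].to_numpy()),
        pdf["s1_peak_t"].to_numpy(),
        pdf["s1_onset_t"].to_numpy(),
    )
    rows = []
    next_free = 0
    for _, ebeat in edf.iterrows():
        q = ebeat["q_t"]
        if np.isnan(q):
            continue
        j = next_free
        while j < len(pdf) and anchors[j] <= q:
            j += 1
        if j >= len(pdf) or anchors[j] - q > max_lag_s:
            continue
        pbeat = pdf.iloc[j]
        next_free = j + 1
        rows.append(
            {
                "window_id": pbeat.get("window_id", 0),
                "q_t": q,
                "r_t": ebeat["r_t"],
                "s_t": ebeat["s_t"],
                "s1_onset_t": pbeat["s1_onset_t"],
                "s1_peak_t": pbeat["s1_peak_t"],
                "s2_peak_t": pbeat["s2_peak_t"],
                "edge": bool(pbeat["edge"]),
            }
        )
    paired = pd.DataFrame(
        rows,
        columns=[
            "window_id", "q_t", "r_t", "s_t",
            "s1_onset_t", "s1_peak_t", "s2_peak_t", "edge",
        ],
    )
    if paired.empty:
        log.warning("beat pairing produced zero pairs")
        paired["rr_ms"] = pd.Series(dtype=float)
        return paired
    rr = np.full(len(paired), np.nan)
    r = paired["r_t"].to_numpy()
    rr[:-1] = np.diff(r) * 1000.0
    paired["rr_ms"] = rr
    return paired


def compute_intervals(paired: pd.DataFrame) -> pd.DataFrame:
    """Add the five systolic intervals (ms) to a paired-beat table.

    Missing constituents (NaN fiducials) propagate to missing intervals.
    """
    if paired.empty:
        out = paired.copy()
        for c in INTERVAL_COLUMNS:
            out[c] = pd.Series(dtype=float)
        return out
    out = paired.copy()
    out["emat_ms"] = (out["s1_onset_t"] - out["q_t"]) * 1000.0
    out["pep_ms"] = (out["s1_peak_t"] - out["q_t"]) * 1000.0
    out["lvet_ms"] = (out["s2_peak_t"] - out["s1_peak_t"]) * 1000.0
    out["lvst_ms"] = (out["s2_peak_t"] - out["s1_onset_t"]) * 1000.0
    out["s1r_ms"] = (out["s1_onset_t"] - out["r_t"]) * 1000.0
    return out


def normalize_intervals(beats: pd.DataFrame) -> pd.DataFrame:
    """Add RR-normalised fractions and the PEP/LVET ratio.

    ``x_pct = x_ms / rr_ms`` is stored as a dimensionless fraction; rendering
    as percent is a presentation concern.  Beats with missing RR get NaN.
    """
    out = beats.copy()
    rr = out["rr_ms"]
    for c in ("emat_ms", "pep_ms", "lvet_ms", "lvst_ms"):
        out[c.replace("_ms", "_pct")] = out[c] / rr
    out["pep_over_lvet"] = out["pep_ms"] / out["lvet_ms"]
    return out


def summarize(beats: pd.DataFrame, exclude_edge: bool = True) -> IntervalSummary:
    """Mean, sample SD, median and IQR per interval, NaNs excluded pairwise.

    Beats flagged as window-edge beats are excluded by default.  The IQR uses
    linear-interpolation quantiles (Q3 - Q1); the SD uses the n-1 convention
    and is NaN for a single value.
    """
    df = beats
    if exclude_edge and "edge" in df.columns:
        n_edge = int(df["edge"].sum())
        if n_edge:
            log.info("excluding %d edge beat(s) from interval statistics", n_edge)
        df = df[~df["edge"].astype(bool)]
    stats: dict[str, dict] = {}
    cols = [c for c in df.columns
            if c in INTERVAL_COLUMNS
            or c.endswith("_pct") or c in ("pep_over_lvet", "rr_ms")]
    for c in cols:
        vals = df[c].dropna().to_numpy(dtype=float)
        if vals.size == 0:
            stats[c] = {"mean": np.nan, "sd": np.nan, "median": np.nan,
                        "iqr": np.nan, "n": 0}
            continue
        q1, q3 = np.percentile(vals, [25, 75])
        stats[c] = {
            "mean": float(vals.mean()),
            "sd": float(np.std(vals, ddof=1)) if vals.size > 1 else float("nan"),
            "median": float(np.median(vals)),
            "iqr": float(q3 - q1),
            "n": int(vals.size),
        }
    return IntervalSummary(stats)


def _flag(value: float, threshold: float, closed: bool) -> bool | None:
    if value is None or np.isnan(value):
        return None
    return bool(value >= threshold) if closed else bool(value > threshold)


def clinical_flags(summary: IntervalSummary, beats: pd.DataFrame | None = None
                   ) -> ClinicalFlags:
    """Screening flags on mean values (per-beat flagging is a config concern).

    EMAT% thresholds are open bounds (> 12.1 %, > 13.8 %); the absolute EMAT
    (>= 104 ms) and EMAT/LVST (>= 0.40) thresholds are closed.
    """
    mean_emat = summary.mean("emat_ms")
    mean_emat_pct = summary.mean("emat_pct")
    mean_lvst = summary.mean("lvst_ms")
    ratio = (
        mean_emat / mean_lvst
        if not (np.isnan(mean_emat) or np.isnan(mean_lvst) or mean_lvst == 0)
        else float("nan")
    )
    return ClinicalFlags(
        emat_pct_gt_12_1=_flag(mean_emat_pct, 0.121, closed=False),
        emat_ge_104ms=_flag(mean_emat, 104.0, closed=True),
        emat_pct_gt_13_8=_flag(mean_emat_pct, 0.138, closed=False),
        emat_over_lvst_ge_0_40=_flag(ratio, 0.40, closed=True),
    )
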
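"""Synthetic synchronized ECG + PCG with programmable ground-truth timing.

The generator emits a beat train in which every fiducial the pipeline is
supposed to find is known by construction:

* the ECG is a sum of Gaussian P/Q/R/S/T deflections per beat;
* S1 is an oscillatory burst built from a low-frequency skeleton (a small
  crest exactly at ``q + EMAT``, a descent to the deepest in-band trough and
  a recovery) plus a high-frequency hump-and-ringdown whose maximum — the
  feature the S1 detector's run-centre + amplitude-gate + refractory cascade
  actually reports — falls exactly at ``q + PEP``.  The skeleton lies below
  the 40 Hz onset low-pass, so the backward-slope onset search terminates at
  the programmed onset; the ringdown lies well above it, so it cannot
  disturb that search;
* S2 is a weaker, higher-frequency burst under a symmetric raised-cosine
  envelope centred at ``s1_peak + LVET``, so that averaging its candidate
  maxima is unbiased.

These morphology choices are the generator's contract with the default
detector thresholds, not a claim of physiological realism; amplitudes, band
placement (S1 content ~30-90 Hz inside the 10-200 Hz band, S2 at 120 Hz) and the
S2-weaker-than-S1 ordering do follow the physiology.  Additive white noise,
baseline wander and per-beat timing jitter are all controlled by one seeded
RNG stream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.io import savemat, wavfile

from .signal_io import RecordingPair, SampledSignal, SourceFormat

__all__ = [
    "BeatTrainSpec",
    "GroundTruth",
    "generate_beat_train",
    "emulate_front_end",
    "write_fixture",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BeatTrainSpec:
    """Study conditions for one synthetic recording.

    Interval defaults reproduce a resting adult with the measured mean
    systolic times (EMAT 74 ms, PEP 89 ms, LVET 244 ms) and 28 beats over a
    20 s observation period (RR ~ 714 ms).
    """

    fs: float = 2000.0
    n_beats: int = 28
    rr_ms: float = 714.0
    rr_jitter_ms: float = 20.0
    emat_ms: float = 74.0
    pep_ms: float = 89.0
    lvet_ms: float = 244.0
    interval_jitter_ms: float = 2.0
    s1_freq_hz: float | None = None   # None: phase-locked, ~50 Hz at defaults
    s2_freq_hz: float = 120.0
    s1_amp: float = 1.0
    s2_amp: float = 0.45
    s1_decay_s: float = 0.020   # ringdown time constant
    s1_trough_frac: float = 0.5  # skeleton trough depth relative to s1_amp
    s1_hump_rise_s: float = 0.004
    s1_prebump_frac: float = 0.1  # initial positive deflection peaking at onset
    s1_prebump_s: float = 0.010
    s1_skel_descent_s: float = 0.016  # skeleton crest-to-trough time
    s1_skel_recover_s: float = 0.020
    s2_width_s: float = 0.100   # raised-cosine S2 width (within 100-140 ms)
    noise_snr_db: float = 20.0  # np.inf disables noise
    wander_amp: float = 0.05
    wander_freq_hz: float = 0.3
    lead_in_s: float = 0.5
    seed: int = 0

    @property
    def lvst_ms(self) -> float:
        return self.lvet_ms + self.pep_ms - self.emat_ms

    def validate(self) -> None:
        if self.fs < 500:
            raise ValueError("fs must be >= 500 Hz for these carriers")
        if self.n_beats < 1:
            raise ValueError("n_beats must be >= 1")
        if self.pep_ms <= self.emat_ms:
            raise ValueError(
                f"PEP ({self.pep_ms} ms) must exceed EMAT ({self.emat_ms} ms): "
                "the S1 peak follows its onset"
            )
        if not 130.0 <= self.lvet_ms <= 400.0:
            raise ValueError(
                f"LVET {self.lvet_ms} ms outside the generable 130-400 ms band "
                "(S2 must fall strictly inside the 125-500 ms search window "
                "and inside the 425 ms S1 refractory period)"
            )
        if self.pep_ms + self.lvet_ms + 80.0 >= self.rr_ms + self.emat_ms:
            raise ValueError(
                "infeasible timing: S2 would collide with the next beat's S1 "
                f"(PEP {self.pep_ms} + LVET {self.lvet_ms} vs RR {self.rr_ms} ms)"
            )
        if not self.s2_amp < self.s1_amp:
            raise ValueError("S2 must be weaker than S1 (s2_amp < s1_amp)")


@dataclass
class GroundTruth:
    """Per-beat fiducial times (seconds) known by construction."""

    q_t: np.ndarray
    r_t: np.ndarray
    s_t: np.ndarray
    s1_onset_t: np.ndarray
    s1_peak_t: np.ndarray
    s2_peak_t: np.ndarray

    @property
    def n_beats(self) -> int:
        return self.r_t.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beat": np.arange(self.n_beats),
                "q_t": self.q_t,
                "r_t": self.r_t,
                "s_t": self.s_t,
                "s1_onset_t": self.s1_onset_t,
                "s1_peak_t": self.s1_peak_t,
                "s2_peak_t": self.s2_peak_t,
            }
        )

    def intervals_ms(self) -> pd.DataFrame:
        """True EMAT/PEP/LVET/LVST/S1R per beat, in ms."""
        return pd.DataFrame(
            {
                "emat_ms": (self.s1_onset_t - self.q_t) * 1000.0,
                "pep_ms": (self.s1_peak_t - self.q_t) * 1000.0,
                "lvet_ms": (self.s2_peak_t - self.s1_peak_t) * 1000.0,
                "lvst_ms": (self.s2_peak_t - self.s1_onset_t) * 1000.0,
                "s1r_ms": (self.s1_onset_t - self.r_t) * 1000.0,
            }
        )


# ECG template: (offset from R [s], amplitude, Gaussian sigma [s]).
# Chosen so the default adaptive thresholds (0.5*max for R, 0.2*max(-ecg)
# for Q/S) succeed; this is the generator contract, not real ECG morphology.
_ECG_WAVES = {
    "p": (-0.180, 0.12, 0.025),
    "q": (-0.040, -0.25, 0.003),
    "r": (0.000, 1.00, 0.010),
    "s": (0.032, -1.00, 0.008),
    "t": (0.280, 0.30, 0.045),
}


def _gauss(t: np.ndarray, center: float, amp: float, sigma: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((t - center) / sigma) ** 2)


def _s1_burst(t: np.ndarray, onset: float, rise: float, spec: BeatTrainSpec
              ) -> np.ndarray:
    """S1 as a negative-leading lobe, a positive hump, and a ringdown.

    Three C1-joined phases define the burst's contract with the detectors:

    0. a gentle in-band positive pre-deflection peaking exactly at ``onset``
       (zero slope there), so that after the 40 Hz zero-phase low-pass the
       crest preceding the main trough — where the backward-slope onset
       search terminates — coincides with ``onset``;
    1. a smooth half-cosine descent from ``onset`` to ``-trough_frac``;
    2. a fast half-cosine rise to the burst maximum ``+s1_amp`` exactly at
       ``onset + rise`` — the first candidate of the squared-threshold
       cascade whose signed amplitude survives the mean-amplitude gate;
    3. a decaying cosine ringdown (carrier ``s1_freq_hz``, default 90 Hz)
       giving the burst its oscillatory 10-200 Hz character while staying
       invisible to the 40 Hz onset low-pass.
    """
    tau_rel = t - onset
    f_ring = spec.s1_freq_hz if spec.s1_freq_hz is not None else 90.0
    d = spec.s1_trough_frac
    w_b = spec.s1_prebump_s
    a_b = spec.s1_prebump_frac
    t_d, t_r = spec.s1_skel_descent_s, spec.s1_skel_recover_s
    active = (tau_rel >= -w_b) & (tau_rel <= rise + 6 * spec.s1_decay_s)
    out = np.zeros_like(t)
    tr = tau_rel[active]

    # Low-frequency skeleton: crest a_b at tau=0, trough -d at t_d, recovery.
    skel = np.zeros_like(tr)
    pre = tr < 0
    skel[pre] = a_b * 0.5 * (1 - np.cos(np.pi * (tr[pre] + w_b) / w_b))
    descend = (tr >= 0) & (tr < t_d)
    skel[descend] = a_b - (d + a_b) * 0.5 * (
        1 - np.cos(np.pi * tr[descend] / t_d))
    recover = (tr >= t_d) & (tr < t_d + t_r)
    skel[recover] = -d * 0.5 * (1 + np.cos(np.pi * (tr[recover] - t_d) / t_r))

    # High-frequency hump + ringdown (invisible to the 40 Hz low-pass).
    hf = np.zeros_like(tr)
    hump = (tr >= rise - spec.s1_hump_rise_s) & (tr < rise)
    hf[hump] = 0.5 * (1 - np.cos(
        np.pi * (tr[hump] - rise + spec.s1_hump_rise_s) / spec.s1_hump_rise_s))
    ring = tr >= rise
    tq = tr[ring] - rise
    hf[ring] = np.cos(2 * np.pi * f_ring * tq) * np.exp(-tq / spec.s1_decay_s)

    out[active] = spec.s1_amp * (skel + hf)
    return out


def _s2_burst(t: np.ndarray, center: float, spec: BeatTrainSpec) -> np.ndarray:
    """Symmetric raised-cosine envelope with a cosine carrier peaking at center."""
    tau_rel = t - center
    half = spec.s2_width_s / 2
    active = np.abs(tau_rel) <= half
    out = np.zeros_like(t)
    tr = tau_rel[active]
    env = np.cos(np.pi * tr / spec.s2_width_s) ** 2
    out[active] = spec.s2_amp * env * np.cos(2 * np.pi * spec.s2_freq_hz * tr)
    return out


def generate_beat_train(spec: BeatTrainSpec) -> tuple[RecordingPair, GroundTruth]:
    """Render one synthetic recording and its ground truth.

    Deterministic given ``spec.seed``; per-beat RR and interval jitters are
    uniform within +/- the stated jitter amplitudes.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_beats

    rr = spec.rr_ms + rng.uniform(-spec.rr_jitter_ms, spec.rr_jitter_ms, n)
    emat = spec.emat_ms + rng.uniform(-spec.interval_jitter_ms,
                                      spec.interval_jitter_ms, n)
    pep = spec.pep_ms + rng.uniform(-spec.interval_jitter_ms,
                                    spec.interval_jitter_ms, n)
    lvet = spec.lvet_ms + rng.uniform(-spec.interval_jitter_ms,
                                      spec.interval_jitter_ms, n)
    if np.any(pep - emat < 2 * spec.s1_hump_rise_s * 1000.0):
        raise ValueError("jitter drove PEP - EMAT too close to the S1 hump "
                         "rise time; reduce jitter or the hump rise")

    r_t = spec.lead_in_s + np.concatenate(([0.0], np.cumsum(rr[:-1]) / 1000.0))
    q_t = r_t + _ECG_WAVES["q"][0]
    s_t = r_t + _ECG_WAVES["s"][0]
    s1_onset = q_t + emat / 1000.0
    s1_peak = q_t + pep / 1000.0
    s2_peak = s1_peak + lvet / 1000.0

    duration = r_t[-1] + rr[-1] / 1000.0 - _ECG_WAVES["q"][0]
    t = np.arange(int(round(duration * spec.fs))) / spec.fs

    ecg = np.zeros_like(t)
    for off, amp, sigma in _ECG_WAVES.values():
        for rk in r_t:
            ecg += _gauss(t, rk + off, amp, sigma)

    pcg = np.zeros_like(t)
    for k in range(n):
        pcg += _s1_burst(t, s1_onset[k], s1_peak[k] - s1_onset[k], spec)
        pcg += _s2_burst(t, s2_peak[k], spec)

    phase = rng.uniform(0, 2 * np.pi, 2)
    wander = spec.wander_amp * np.sin(2 * np.pi * spec.wander_freq_hz * t
                                      + phase[0])
    ecg = ecg + wander
    pcg = pcg + 0.3 * spec.wander_amp * np.sin(
        2 * np.pi * spec.wander_freq_hz * t + phase[1])

    if np.isfinite(spec.noise_snr_db):
        scale = 10.0 ** (-spec.noise_snr_db / 20.0)
        ecg = ecg + rng.normal(0, np.sqrt(np.mean(ecg**2)) * scale, t.size)
        pcg = pcg + rng.normal(0, np.sqrt(np.mean(pcg**2)) * scale, t.size)

    pair = RecordingPair(
        SampledSignal(pcg, spec.fs, 0.0),
        SampledSignal(ecg, spec.fs, 0.0),
        SourceFormat.SYNTH,
        label=f"synthetic beat train (seed={spec.seed})",
    )
    truth = GroundTruth(q_t, r_t, s_t, s1_onset, s1_peak, s2_peak)
    return pair, truth


def emulate_front_end(pair: RecordingPair) -> RecordingPair:
    """Causal acquisition-chain emulation for robustness testing.

    Applies 2nd-order causal low-pass filters (100 Hz on PCG, 15 Hz on ECG)
    and the firmware's mid-sample PCG averaging, approximated by averaging
    each sample with its predecessor (a half-sample delay).
    """
    fs = pair.fs
    if fs <= 200:
        raise ValueError("front-end emulation needs fs > 200 Hz")
    sos_pcg = sps.butter(2, 100.0, btype="low", fs=fs, output="sos")
    sos_ecg = sps.butter(2, 15.0, btype="low", fs=fs, output="sos")
    pcg = sps.sosfilt(sos_pcg, pair.pcg.samples)
    pcg = 0.5 * (pcg + np.concatenate(([pcg[0]], pcg[:-1])))
    ecg = sps.sosfilt(sos_ecg, pair.ecg.samples)
    return RecordingPair(
        SampledSignal(pcg, fs, pair.pcg.t0),
        SampledSignal(ecg, fs, pair.ecg.t0),
        pair.source_format,
        pair.label + " [front-end]",
    )


def write_fixture(pair: RecordingPair, truth: GroundTruth | None,
                  out_dir: str | Path) -> dict[str, Path]:
    """Write a fixture directory readable by :mod:`systoseg.signal_io`.

    Emits ``recording.csv`` (serial-plotter dialect: timestamp-ms, pcg, ecg),
    ``pcg.wav`` (float32 mono), ``recording.mat`` (``pcg``/``ecg`` vectors)
    and, when ground truth is given, ``truth.csv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    t_ms = (pair.pcg.t0 + np.arange(len(pair.pcg)) / pair.fs) * 1000.0
    csv_path = out_dir / "recording.csv"
    pd.DataFrame(
        {"t_ms": t_ms, "pcg": pair.pcg.samples, "ecg": pair.ecg.samples}
    ).to_csv(csv_path, index=False, header=False, float_format="%.6f")
    paths["csv"] = csv_path

    wav_path = out_dir / "pcg.wav"
    wavfile.write(wav_path, int(round(pair.fs)),
                  pair.pcg.samples.astype(np.float32))
    paths["wav"] = wav_path

    mat_path = out_dir / "recording.mat"
    savemat(mat_path, {"pcg": pair.pcg.samples, "ecg": pair.ecg.samples,
                       "fs": pair.fs})
    paths["mat"] = mat_path

    if truth is not None:
        truth_path = out_dir / "truth.csv"
        truth.to_frame().to_csv(truth_path, index=False, float_format="%.6f")
        paths["truth"] = truth_path
    return paths
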
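"""Offline conditioning filters applied before segmentation.

The ECG is detrended and high-passed at 2 Hz (4th-order IIR, zero-phase) to
remove baseline wander without shifting QRS fiducials; the PCG is only
detrended for peak detection, and additionally low-passed at 40 Hz when
searching for the S1 onset, where the slow initial deflection matters more
than the oscillatory burst itself.

All offline filters are Butterworth designs specified by their half-power
(-3 dB) cutoff and applied forward-backward (``sosfiltfilt``), so the net
response is zero-phase and the amplitude attenuation doubles in dB.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signal_io import SampledSignal

__all__ = [
    "FilterSpec",
    "apply_zero_phase",
    "condition_ecg",
    "condition_pcg",
    "lowpass_for_onset",
]

#: Defaults mirror the segmentation algorithm's filter chain.
ECG_HIGHPASS = None  # populated below, after FilterSpec is defined
PCG_ONSET_LOWPASS = None


@dataclass(frozen=True)
class FilterSpec:
    """An IIR filter specification (half-power cutoff convention)."""

    kind: str  # "highpass" | "lowpass"
    order: int
    cutoff_hz: float
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("highpass", "lowpass"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if self.cutoff_hz <= 0:
            raise ValueError("cutoff must be positive")

    def sos(self, fs: float) -> np.ndarray:
        if self.cutoff_hz >= fs / 2:
            raise ValueError(
                f"cutoff {self.cutoff_hz} Hz is not below Nyquist ({fs / 2} Hz)"
            )
        btype = "high" if self.kind == "highpass" else "low"
        return sps.butter(self.order, self.cutoff_hz, btype=btype, fs=fs,
                          output="sos")


ECG_HIGHPASS = FilterSpec("highpass", order=4, cutoff_hz=2.0)
PCG_ONSET_LOWPASS = FilterSpec("lowpass", order=4, cutoff_hz=40.0)


def apply_zero_phase(sig: SampledSignal, spec: FilterSpec) -> SampledSignal:
    """Apply ``spec`` forward-backward; output length equals input length.

    Edge transients are handled by the default odd-reflection padding of
    ``sosfiltfilt``, which keeps results reproducible bit-for-bit on a
    platform.
    """
    filtered = sps.sosfiltfilt(spec.sos(sig.fs), sig.samples)
    return SampledSignal(filtered, sig.fs, sig.t0)


def condition_ecg(
    ecg: SampledSignal, spec: FilterSpec = ECG_HIGHPASS
) -> SampledSignal:
    """Detrend then high-pass the ECG (default: 2 Hz, order 4, zero-phase)."""
    if ecg.fs <= 2 * spec.cutoff_hz:
        raise ValueError(
            f"sampling rate {ecg.fs} Hz too low for a {spec.cutoff_hz} Hz "
            "high-pass"
        )
    detrended = sps.detrend(ecg.samples, type="linear")
    return apply_zero_phase(SampledSignal(detrended, ecg.fs, ecg.t0), spec)


def condition_pcg(pcg: SampledSignal) -> SampledSignal:
    """Mean-subtract and linearly detrend the PCG; no filtering."""
    x = pcg.samples - pcg.samples.mean()
    return SampledSignal(sps.detrend(x, type="linear"), pcg.fs, pcg.t0)


def lowpass_for_onset(
    pcg: SampledSignal, spec: FilterSpec = PCG_ONSET_LOWPASS
) -> SampledSignal:
    """Zero-phase low-pass (default 40 Hz) used only for S1 onset search."""
    if pcg.fs <= 2 * spec.cutoff_hz:
        raise ValueError(
            f"sampling rate {pcg.fs} Hz too low for a {spec.cutoff_hz} Hz "
            "low-pass"
        )
    return apply_zero_phase(pcg, spec)
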
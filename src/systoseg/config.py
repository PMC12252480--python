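"""Pipeline configuration, serialisable to YAML/JSON.

Defaults equal the segmentation algorithm's printed constants: squared-PCG
threshold fraction 0.1, amplitude gate 0.5, 425 ms S1 refractory period,
125-500 ms S2 window, 40 % amplitude-consistency tolerance, 0.2 s onset
trough spacing, 50 ms onset validation tolerance, R threshold fraction 0.5,
Q/S threshold fraction 0.2, 250 ms QRS search windows, 2 Hz ECG high-pass,
40 Hz onset low-pass, 10 s analysis windows.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .ecg_seg import QrsDetectorParams
from .pcg_seg import OnsetParams, S1DetectorParams, S2Params
from .preprocess import FilterSpec

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    window_s: float = 10.0
    edge_margin_s: float = 0.1
    pairing_max_lag_s: float = 0.250
    s1: S1DetectorParams = field(default_factory=S1DetectorParams)
    s2: S2Params = field(default_factory=S2Params)
    onset: OnsetParams = field(default_factory=OnsetParams)
    qrs: QrsDetectorParams = field(default_factory=QrsDetectorParams)
    ecg_highpass: FilterSpec = field(
        default_factory=lambda: FilterSpec("highpass", 4, 2.0))
    onset_lowpass: FilterSpec = field(
        default_factory=lambda: FilterSpec("lowpass", 4, 40.0))
    loa_multiplier: float | str = 1.96

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        kwargs = dict(data)
        for key, sub in (
            ("s1", S1DetectorParams),
            ("s2", S2Params),
            ("onset", OnsetParams),
            ("qrs", QrsDetectorParams),
            ("ecg_highpass", FilterSpec),
            ("onset_lowpass", FilterSpec),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
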
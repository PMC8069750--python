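"""Pipeline configuration: every tunable parameter with its published default.

Defaults reproduce the printed analysis parameters: 50 Hz sampling, 30 mm
proxy noise, 0.3 Hz / 5th-order zero-phase low-pass for the local frame
origin, 0.7 m/s peak prominence with 0.8 s minimum separation for cycle
detection, 12-point cycle resampling with +/-6-lag cross-correlation, a
256-sample Hanning / 512-point FFT / hop-1 STFT, and decision thresholds
T_tuck = 40 m/s, T_G5 = 100 m/s, T_turn = 10 deg/s.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Tuple

import yaml


@dataclass
class Thresholds:
    """Hard decision-rule thresholds of the classification tree."""

    t_tuck: float = 40.0   # m/s, sideways 0.5-1.0 Hz band sum; below -> Tuck
    t_g5: float = 100.0    # m/s, vertical 0.5-1.5 Hz band sum; below -> G5
    t_turn: float = 10.0   # deg/s, per-cycle heading rate; above -> Turn

    def __post_init__(self) -> None:
        if min(self.t_tuck, self.t_g5, self.t_turn) <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class StftConfig:
    window: int = 256      # Hanning window length, samples
    nfft: int = 512        # zero-padded FFT length
    hop: int = 1           # 255-sample overlap -> one frame per sample
    band_side: Tuple[float, float] = (0.5, 1.0)  # Hz, closed band
    band_vert: Tuple[float, float] = (0.5, 1.5)  # Hz, closed band

    def __post_init__(self) -> None:
        if self.window < 2 or self.nfft < self.window or self.hop < 1:
            raise ValueError("invalid STFT configuration")


@dataclass
class PipelineConfig:
    sample_rate: float = 50.0     # Hz
    noise_sd: float = 0.030       # m, expected position noise (spline target)
    cutoff_hz: float = 0.3        # origin low-pass cutoff
    butter_order: int = 5
    prominence: float = 0.7       # m/s, sideways velocity peak prominence
    min_separation: float = 0.8   # s, minimum peak spacing
    min_speed: float = 0.1        # m/s, below this the frame is undefined
    edge_guard_periods: float = 1.0  # cycles excluded within this many
    # cutoff periods (1/cutoff_hz) of a block edge, where the zero-phase
    # low-pass origin is still settling
    n_resample: int = 12          # points per cycle
    max_lag: int = 6              # cross-correlation lags
    min_overlap: float = 0.5      # cycle matching overlap fraction
    stft: StftConfig = field(default_factory=StftConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed_noise: int = 0
    seed_split: int = 0
    seed_init: int = 0

    def __post_init__(self) -> None:
        for name in ("sample_rate", "cutoff_hz", "butter_order", "prominence",
                     "min_separation", "min_speed", "n_resample", "max_lag",
                     "min_overlap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "stft" in d and isinstance(d["stft"], dict):
            stft = dict(d["stft"])
            for key in ("band_side", "band_vert"):
                if key in stft:
                    stft[key] = tuple(stft[key])
            d["stft"] = StftConfig(**stft)
        if "thresholds" in d and isinstance(d["thresholds"], dict):
            d["thresholds"] = Thresholds(**d["thresholds"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


__all__ = ["Thresholds", "StftConfig", "PipelineConfig"]
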
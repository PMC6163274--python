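"""Pipeline configuration: every constant the method leaves open, in one place.

Defaults are the package's documented choices (filter stopband, detector
windows, JNC7 thresholds, classifier hyperparameters...); a YAML file can
override any subset, and unknown keys are rejected so typos cannot silently
fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    fs: float = 125.0
    # PPG filter (Chebyshev II band-pass)
    ppg_low: float = 0.5
    ppg_high: float = 10.0
    ppg_order: int = 4
    ppg_stopband_db: float = 20.0
    # ECG filter (Butterworth band-pass)
    ecg_low: float = 0.5
    ecg_high: float = 40.0
    ecg_order: int = 4
    # edge margin excluded from beat extraction (s)
    margin_s: float = 1.0
    # R-peak detector windows (s) and threshold offset
    w_peak: float = 0.097
    w_beat: float = 0.611
    beta: float = 0.08
    refractory: float = 0.2
    # fiducial search windows (s)
    a_window: float = 0.040
    diastole_window: float = 0.35
    # JNC7 systolic thresholds (mmHg)
    thresholds: tuple[float, float] = (120.0, 140.0)
    # classifier hyperparameters
    knn_k: int = 5
    adaboost_n: int = 50
    bagged_n: int = 100
    logistic_c: float = 1.0
    test_size: float = 0.3
    cv_folds: int = 10
    # evaluation seeds
    seeds: list[int] = field(default_factory=lambda: list(range(10)))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "thresholds" in d:
            d = {**d, "thresholds": tuple(d["thresholds"])}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
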
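"""Experiment configuration: one flat, validated record of every knob.

The defaults reproduce the reference study conditions: an 8-subject cohort,
two sessions, 30 s eyes-closed recordings and a 120-word visual-stimulation
session at 256 Hz, a 1-55 Hz FIR band-pass, 5-fold cross-validation and a
degree-3 polynomial SVM.  Configurations round-trip through a plain YAML
key-value file, and every run embeds the resolved configuration (and its
hash) in its outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class ExperimentConfig:
    # cohort
    n_subjects: int = 8
    sessions: int = 2
    separation: float = 1.0
    intra_subject_var: float = 0.1
    seed: int = 0

    # protocols
    fs: float = 256.0
    ec_duration_s: float = 30.0
    vs_n_stimuli: int = 120

    # generator amplitudes (microvolts)
    alpha_amplitude_uv: float = 10.0
    background_amplitude_uv: float = 5.0
    sensor_noise_uv: float = 2.0
    blink_rate_hz: float = 0.2
    blink_amplitude_uv: float = 150.0

    # preprocessing
    low_hz: float = 1.0
    high_hz: float = 55.0
    discard_s: float = 5.0
    frame_s: float = 1.0
    pre_s: float = 0.5
    post_s: float = 1.5
    amp_thresh_uv: float = 100.0
    ocular_method: str = "regression"

    # classifier
    degree: int = 3
    coef0: float = 1.0
    gamma: float | None = None  # None -> 1 / n_features
    C: float = 1.0
    strategies: tuple[str, ...] = ("OVO", "OVA")

    # evaluation
    k: int = 5
    f1_mode: str = "standard"
    stratify: bool = True
    averaging: str = "macro"
    alpha: float = 0.05
    nonparametric: str = "ranksum"

    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.sessions < 1:
            raise ValueError("sessions must be >= 1")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if not 0 < self.low_hz < self.high_hz < self.fs / 2:
            raise ValueError("need 0 < low_hz < high_hz < fs/2")
        if self.vs_n_stimuli < 1:
            raise ValueError("vs_n_stimuli must be >= 1")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.ocular_method not in ("regression", "off"):
            raise ValueError("ocular_method must be 'regression' or 'off'")
        for s in self.strategies:
            if s not in ("OVO", "OVA"):
                raise ValueError(f"unknown strategy {s!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["strategies"] = list(self.strategies)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "strategies" in data:
            data = {**data, "strategies": tuple(data["strategies"])}
        return cls(**data)
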
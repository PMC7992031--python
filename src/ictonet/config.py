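"""Declarative study configuration.

One YAML document collects every stage's parameters; unknown keys are
rejected so typos cannot silently fall back to defaults.  The defaults are
the pipeline's standard constants: 8--13 Hz band, 250 Hz target rate,
first 200 s cut into ten 20 s segments, 99 IAAFT surrogates with 10
iterations, per-connection 95% significance level.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .dynamics import ThetaParams
from .synth import GroundTruthSpec

__all__ = ["StudyConfig", "SynthConfig", "PreprocessConfig", "NetworkConfig", "BNIConfig"]


@dataclass(frozen=True)
class SynthConfig:
    n_controls: int = 26
    n_patients: int = 26
    n_regions: int = 90
    fs: float = 600.0
    duration: float = 300.0
    band: tuple[float, float] = (8.0, 13.0)
    envelope_timescale: float = 0.3
    base_density: float = 0.15
    base_strength: float = 0.5
    patient_effect: float = 1.6
    patient_effect_on: str = "density"
    leakage_strength: float = 0.15
    sensor_noise: float = 0.2
    log_amp_sigma: float = 0.5

    def ground_truth_spec(self, seed: int = 0) -> GroundTruthSpec:
        return GroundTruthSpec(
            n_regions=self.n_regions, fs=self.fs, duration=self.duration,
            band=tuple(self.band), envelope_timescale=self.envelope_timescale,
            base_density=self.base_density, base_strength=self.base_strength,
            patient_effect=self.patient_effect,
            patient_effect_on=self.patient_effect_on,
            leakage_strength=self.leakage_strength,
            sensor_noise=self.sensor_noise, log_amp_sigma=self.log_amp_sigma,
            seed=seed,
        )


@dataclass(frozen=True)
class PreprocessConfig:
    low_hz: float = 8.0
    high_hz: float = 13.0
    target_fs: float = 250.0
    total_s: float = 200.0
    segment_s: float = 20.0

    def __post_init__(self):
        n = self.total_s / self.segment_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError("segment_s must divide total_s")

    @property
    def n_segments(self) -> int:
        return int(round(self.total_s / self.segment_s))


@dataclass(frozen=True)
class NetworkConfig:
    n_surrogates: int = 99
    n_iterations: int = 10
    alpha: float = 0.05
    clip_negative: bool = True

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        min_p = 1.0 / (self.n_surrogates + 1)
        if min_p > self.alpha:
            raise ValueError(
                f"{self.n_surrogates} surrogates cannot attain alpha={self.alpha} "
                f"(minimum rank p-value is {min_p:.3g}); increase n_surrogates"
            )


@dataclass(frozen=True)
class DynamicsConfig:
    i0: float = -1.2
    noise_scale: float = 1.0
    dt: float = 0.01
    t_total: float = 2000.0
    t_transient: float = 100.0
    rest_margin: float = 1.0
    t_close: float = 1.5

    def theta_params(self, seed: int = 0) -> ThetaParams:
        return ThetaParams(i0=self.i0, noise_scale=self.noise_scale, dt=self.dt,
                           t_total=self.t_total, t_transient=self.t_transient,
                           rest_margin=self.rest_margin, t_close=self.t_close,
                           seed=seed)


@dataclass(frozen=True)
class BNIConfig:
    n_grid: int = 16
    n_realizations: int = 2
    calibration_targets: tuple[float, float] = (0.05, 0.95)
    n_reference: int = 4  # held-out control-like networks for calibration
    k_start: float = 1.0
    normalized: bool = True


@dataclass(frozen=True)
class StudyConfig:
    seed: int = 0
    synth: SynthConfig = field(default_factory=SynthConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    dynamics: DynamicsConfig = field(default_factory=DynamicsConfig)
    bni: BNIConfig = field(default_factory=BNIConfig)

    @classmethod
    def from_dict(cls, doc: dict) -> "StudyConfig":
        return _build(cls, doc or {}, "")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _build(cls, doc: dict, prefix: str):
    if not isinstance(doc, dict):
        raise ValueError(f"section {prefix or '<root>'} must be a mapping")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(doc) - set(fields)
    if unknown:
        raise ValueError(f"unknown config keys in {prefix or '<root>'}: {sorted(unknown)}")
    kwargs = {}
    for name, value in doc.items():
        ftype = fields[name].type
        nested = {
            "synth": SynthConfig, "preprocess": PreprocessConfig,
            "network": NetworkConfig, "dynamics": DynamicsConfig, "bni": BNIConfig,
        }.get(name)
        if nested is not None:
            kwargs[name] = _build(nested, value, f"{prefix}{name}.")
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)
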
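"""Run configuration: schema-validated YAML/JSON with defaults.

A :class:`RunConfig` collects everything a full pipeline run needs —
stimulus geometry and motion, generator settings, decoder grid, speller
timing, and the master seed.  Loading validates strictly: unknown keys are
rejected by name so typos never pass silently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "save_config", "config_hash"]


class ConfigError(ValueError):
    pass


def _from_dict(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ConfigError(f"section '{path}' must be a mapping")
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in section '{path}' "
            f"(known: {sorted(known)})"
        )
    kwargs = {}
    for name, value in data.items():
        f = known[name]
        if dataclasses.is_dataclass(f.type) or dataclasses.is_dataclass(
            getattr(f.type, "__origin__", None)
        ):
            kwargs[name] = _from_dict(f.type, value, f"{path}.{name}")
        elif isinstance(value, dict) and dataclasses.is_dataclass(_SECTION_TYPES.get(name)):
            kwargs[name] = _from_dict(_SECTION_TYPES[name], value, f"{path}.{name}")
        else:
            kwargs[name] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as err:
        raise ConfigError(f"invalid value in section '{path}': {err}") from err


@dataclass(frozen=True)
class StimulusConfig:
    outer_diameter_px: float = 100.0
    inner_diameter_px: float = 20.0
    n_rings: int = 8
    n_sectors: int = 16
    l_max: float = 1.0
    l_min: float = 0.0
    pixel_pitch_mm: float = 0.31
    viewing_distance_mm: float = 800.0
    reversal_freq_hz: float = 15.6
    amplitude_px: float = 10.0
    refresh_rate_hz: float = 144.0
    duration_s: float = 1.0
    resolution: int = 200


@dataclass(frozen=True)
class GeneratorConfig:
    paradigm: str = "ssmvep"  # "ssmvep" | "ssvep"
    contrast: float = 1.0
    trial_duration_s: float = 5.0
    fs_hz: float = 1200.0
    latency_s: float = 0.150
    noise_scale: float = 1.0
    frequencies: tuple = ()
    trials_per_freq: int = 1

    def __post_init__(self) -> None:
        if self.paradigm not in ("ssmvep", "ssvep"):
            raise ValueError(f"paradigm must be 'ssmvep' or 'ssvep', got {self.paradigm!r}")
        object.__setattr__(self, "frequencies", tuple(self.frequencies))


@dataclass(frozen=True)
class DecoderConfig:
    f_start_hz: float = 7.0
    f_stop_hz: float = 14.8
    f_step_hz: float = 0.2
    n_harmonics: int = 1
    latency_s: float = 0.150


@dataclass(frozen=True)
class SpellerConfig:
    stimulation_time_s: float = 3.0
    n_blocks: int = 6
    gaze_shift_s: float = 0.5


_SECTION_TYPES = {
    "stimulus": StimulusConfig,
    "generator": GeneratorConfig,
    "decoder": DecoderConfig,
    "speller": SpellerConfig,
}


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    output_dir: str = "."
    stimulus: StimulusConfig = field(default_factory=StimulusConfig)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    decoder: DecoderConfig = field(default_factory=DecoderConfig)
    speller: SpellerConfig = field(default_factory=SpellerConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def candidate_freqs(self):
        import numpy as np

        d = self.decoder
        n = int(round((d.f_stop_hz - d.f_start_hz) / d.f_step_hz)) + 1
        return np.round(d.f_start_hz + d.f_step_hz * np.arange(n), 4)


def load_config(path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = yaml.safe_load(path.read_text())
    if data is None:
        data = {}
    return _from_dict(RunConfig, data, "run")


def save_config(path, config: RunConfig) -> Path:
    path = Path(path)
    d = config.to_dict()
    # tuples -> lists for clean YAML round-trip
    d["generator"]["frequencies"] = list(d["generator"]["frequencies"])
    path.write_text(yaml.safe_dump(d, sort_keys=True))
    return path


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the full configuration, for run logs."""
    blob = json.dumps(config.to_dict(), sort_keys=True, default=list)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
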
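"""Run configuration for the calibrate → estimate workflow.

Values resolve with precedence CLI flags > config file (YAML key-value) >
defaults below. The defaults are the acquisition/analysis parameters of a
standard cyclical-contraction protocol: 2 kHz sampling, 10–400 Hz
band-pass with a 50 Hz notch, 10,240/2,560 ms MF windows, EEMD on IMF1,
and N = 3 fatigue levels (non-fatigued / transitional / fully fatigued).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .errors import ParameterError


@dataclass
class RunConfig:
    sampling_rate: float = 2000.0
    band_low: float = 10.0
    band_high: float = 400.0
    notch_hz: float = 50.0
    notch_q: float = 30.0
    window_ms: float = 10240.0
    step_ms: float = 2560.0
    ensemble_size: int = 100
    noise_ratio: float = 0.2
    max_imfs: int = 8
    seed: int = 0
    n_levels: int = 3
    imf_index: int = 1

    def __post_init__(self) -> None:
        for name in ("sampling_rate", "band_low", "band_high", "notch_hz",
                     "notch_q", "window_ms", "step_ms"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive, got {getattr(self, name)}")
        if self.window_ms <= self.step_ms:
            raise ParameterError(
                f"window_ms ({self.window_ms}) must exceed step_ms ({self.step_ms})"
            )
        if self.imf_index < 1:
            raise ParameterError(f"imf_index must be >= 1, got {self.imf_index}")
        if self.n_levels < 2:
            raise ParameterError(f"n_levels must be >= 2, got {self.n_levels}")
        if self.ensemble_size < 1:
            raise ParameterError(f"ensemble_size must be >= 1, got {self.ensemble_size}")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus CLI overrides."""
    values: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ParameterError(f"config file {path} must hold key: value pairs")
        values.update(loaded)
    for key, val in (overrides or {}).items():
        if val is not None:
            values[key] = val
    known = {f.name for f in fields(RunConfig)}
    unknown = set(values) - known
    if unknown:
        raise ParameterError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**values)
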
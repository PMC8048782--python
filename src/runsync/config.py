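"""Run configuration: the fixed constants of the measurement protocol.

Every field has a default equal to the protocol constant it represents
(4-minute runs, 60/30 s analysis trims, 1 % tempo tolerance, 0.75 RVL
cutoff, 9.97 m rod spacing on a 289 m track, 100 Hz gyroscope and 250 Hz
sonar sampling, 120-step tempo adaptation, 8-step cadence window), so an
empty configuration file is a valid configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class RunConfig:
    session_duration: float = 240.0  # s
    trim_start: float = 60.0         # s discarded at the start of a run
    trim_end: float = 30.0           # s discarded at the end of a run
    tempo_tolerance: float = 0.01    # fractional SPM/BPM mismatch allowed
    rvl_cutoff: float = 0.75         # entrainer classification threshold
    rod_spacing: float = 9.97        # m between speed-marker rods
    gyro_rate: float = 100.0         # Hz
    sonar_rate: float = 250.0        # Hz
    adaptation_steps: int = 120      # steps used for the adaptive music tempo
    cadence_window: int = 8          # same-leg steps per cadence window
    rng_seed: int = 0

    # track geometry and sensor-synthesis constants
    track_length: float = 289.0      # m, circular track
    n_rods: int = 29
    gyro_noise_sd: float = 0.02      # additive noise, signal amplitude = 1
    sonar_noise_sd: float = 0.05     # m
    sonar_far: float = 6.0           # m, plateau distance away from rods
    sonar_near: float = 1.0          # m, dip minimum at a rod
    sonar_dip_halfwidth: float = 0.15  # s, half width of the V-shaped dip

    def __post_init__(self) -> None:
        if self.trim_start + self.trim_end >= self.session_duration:
            raise ConfigError(
                "trim_start + trim_end must be smaller than session_duration "
                f"({self.trim_start} + {self.trim_end} >= {self.session_duration})"
            )
        if self.tempo_tolerance <= 0:
            raise ConfigError("tempo_tolerance must be > 0")
        if not 0.0 <= self.rvl_cutoff <= 1.0:
            raise ConfigError("rvl_cutoff must lie in [0, 1]")
        for name in ("rod_spacing", "gyro_rate", "sonar_rate", "track_length"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.cadence_window < 2:
            raise ConfigError("cadence_window must be >= 2")
        if self.adaptation_steps < 1:
            raise ConfigError("adaptation_steps must be >= 1")

    @property
    def analysis_window(self) -> tuple[float, float]:
        """Closed [start, end] interval retained for feature computation."""
        return (self.trim_start, self.session_duration - self.trim_end)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a flat key: value configuration file (YAML syntax).

        Missing keys take their defaults; unknown keys are rejected.
        """
        text = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a flat key-value mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
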
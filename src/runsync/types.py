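"""Core in-memory containers shared across the pipeline.

All times are seconds from the start of a running session (t = 0 at "go");
positions are 1-D coordinates in meters along the (circular) track.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

FEET = ("left", "right")

#: Conditions that enter the analysis, in protocol order.
ANALYZED_CONDITIONS = ("no_music", "uninstructed", "instructed")
#: Conditions with a music stimulus.
MUSIC_CONDITIONS = ("uninstructed", "instructed")


class ValidationError(ValueError):
    """Raised when input data violates a structural contract."""


@dataclass(frozen=True)
class StepEvent:
    """One footfall: time, foot, and heel position along the track."""

    t: float
    foot: str
    heel_x: float

    def __post_init__(self) -> None:
        if self.foot not in FEET:
            raise ValidationError(f"unknown foot label {self.foot!r}; expected one of {FEET}")
        if self.t < 0:
            raise ValidationError(f"negative event time {self.t}")


def step_times(events: list[StepEvent]) -> np.ndarray:
    return np.array([e.t for e in events], dtype=float)


def heel_positions(events: list[StepEvent]) -> np.ndarray:
    return np.array([e.heel_x for e in events], dtype=float)


@dataclass
class BeatSchedule:
    """Musical beat times with the instantaneous tempo at each beat.

    Beat times are strictly increasing; ``bpm`` holds the tempo in beats
    per minute at each beat (constant for an isochronous stimulus).
    """

    times: np.ndarray
    bpm: np.ndarray
    stretch_factor: Optional[float] = None  # bpm / original track tempo

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.bpm = np.asarray(self.bpm, dtype=float)
        if self.times.ndim != 1 or self.bpm.shape != self.times.shape:
            raise ValidationError("beat times and bpm must be 1-D arrays of equal length")
        if self.times.size == 0:
            raise ValidationError("a beat schedule needs at least one beat")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValidationError("beat times must be strictly increasing")
        if np.any(self.bpm <= 0):
            raise ValidationError("bpm values must be positive")

    def __len__(self) -> int:
        return int(self.times.size)

    def bpm_at(self, t: np.ndarray | float) -> np.ndarray | float:
        """Tempo at time ``t``, linearly interpolated between beats."""
        return np.interp(t, self.times, self.bpm)


@dataclass
class SensorTrace:
    """A uniformly sampled scalar signal (angular velocity or sonar distance)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValidationError("trace times and values must be 1-D arrays of equal length")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def rate(self) -> float:
        """Sampling rate in Hz (requires >= 2 samples)."""
        if len(self) < 2:
            raise ValidationError("rate undefined for traces with < 2 samples")
        return 1.0 / float(np.mean(np.diff(self.times)))

    def check_uniform(self, rtol: float = 1e-6) -> None:
        if len(self) < 2:
            return
        dt = np.diff(self.times)
        if not np.allclose(dt, dt[0], rtol=rtol, atol=1e-9):
            raise ValidationError("trace is not uniformly sampled")


@dataclass
class SessionRecord:
    """One 4-minute run of one runner under one condition."""

    runner_id: str
    condition: str
    duration: float
    step_events: list[StepEvent]
    beat_schedule: Optional[BeatSchedule] = None
    gyro_left: Optional[SensorTrace] = None
    gyro_right: Optional[SensorTrace] = None
    sonar: Optional[SensorTrace] = None
    #: simulator-only ground truth: (times s, speed km/h)
    true_speed_profile: Optional[tuple[np.ndarray, np.ndarray]] = None

    def __post_init__(self) -> None:
        if self.condition not in ANALYZED_CONDITIONS:
            raise ValidationError(
                f"unknown condition {self.condition!r}; expected one of {ANALYZED_CONDITIONS}"
            )
        ts = step_times(self.step_events)
        if ts.size and (ts.min() < 0 or ts.max() > self.duration):
            raise ValidationError("step event times must lie in [0, duration]")
        for foot in FEET:
            ft = np.array([e.t for e in self.step_events if e.foot == foot])
            if ft.size > 1 and not np.all(np.diff(ft) > 0):
                raise ValidationError(f"{foot}-foot step times must be strictly increasing")
        if (self.beat_schedule is not None) != (self.condition in MUSIC_CONDITIONS):
            raise ValidationError(
                "beat schedule must be present exactly for music conditions "
                f"(condition={self.condition!r})"
            )

    @property
    def has_music(self) -> bool:
        return self.beat_schedule is not None


@dataclass
class EntrainmentSummary:
    """Per-session entrainment metrics.

    ``mean_rpa`` is None whenever ``rvl`` falls below the classification
    cutoff: a mean phase angle is only meaningful when the phase relation
    is consistent enough.
    """

    tempo_entrainment: float     # percent of tempo-entrained steps, [0, 100]
    mean_rpa: Optional[float]    # degrees in (-180, 180], None when gated
    rvl: float                   # resultant vector length, [0, 1]
    is_entrainer: bool
    n_steps_analyzed: int
    raw_angles: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.tempo_entrainment <= 100.0:
            raise ValidationError("tempo_entrainment must lie in [0, 100]")
        if not 0.0 <= self.rvl <= 1.0 + 1e-12:
            raise ValidationError("rvl must lie in [0, 1]")
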
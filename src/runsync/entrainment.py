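"""Session-level entrainment metrics.

For a run with music, four quantities describe how the runner's steps
relate to the beat:

* tempo entrainment — percentage of steps whose instantaneous cadence
  lies within a tolerance (default 1 %) of the concurrent music tempo;
* per-step relative phase angles and their circular mean;
* the resultant vector length (RVL) of those angles;
* an entrainer flag: RVL at or above the cutoff (default 0.75).

The mean phase angle is reported only when the RVL reaches the cutoff —
an average direction of an incoherent phase distribution carries no
information. The first 60 s (start-up) and final 30 s (anticipated
ending) of each run are excluded before any feature is computed.
"""

from __future__ import annotations

import logging
from typing import Sequence, TypeVar

import numpy as np

from .circular import circular_mean, relative_phases, resultant_vector_length
from .config import RunConfig
from .kinematics import cadence_series
from .types import EntrainmentSummary, SessionRecord, StepEvent, ValidationError

logger = logging.getLogger(__name__)

T = TypeVar("T")


class UndefinedScoreError(ValueError):
    """No steps were available to score."""


def trim_window(items: Sequence[T], duration: float, trim_start: float,
                trim_end: float, key=lambda item: item.t) -> list[T]:
    """Keep items whose time lies in the closed window [trim_start, duration - trim_end]."""
    if trim_start + trim_end >= duration:
        raise ValueError("trim_start + trim_end must be smaller than duration")
    lo, hi = trim_start, duration - trim_end
    return [item for item in items if lo <= key(item) <= hi]


def tempo_entrainment(cadence_t: np.ndarray, cadence_spm: np.ndarray,
                      step_times: np.ndarray, beats, tolerance: float = 0.01) -> float:
    """Percentage of tempo-entrained steps.

    A step is tempo-entrained when the cadence current at the step (most
    recent moving-average value at or before the step time, a causal hold)
    differs from the music tempo at that moment by at most ``tolerance``
    (fractional). Steps taken before the first cadence value exists are
    not scored.
    """
    st = np.asarray(step_times, dtype=float)
    cadence_t = np.asarray(cadence_t, dtype=float)
    if cadence_t.size == 0:
        raise UndefinedScoreError("no cadence values: cannot score tempo entrainment")
    idx = np.searchsorted(cadence_t, st, side="right") - 1
    scored = idx >= 0
    if not scored.any():
        raise UndefinedScoreError("no steps with a defined cadence value")
    spm = np.asarray(cadence_spm, dtype=float)[idx[scored]]
    bpm = np.asarray(beats.bpm_at(st[scored]), dtype=float)
    entrained = np.abs(spm - bpm) <= tolerance * bpm
    return 100.0 * float(np.count_nonzero(entrained)) / float(entrained.size)


def classify_entrainer(rvl: float, cutoff: float = 0.75) -> bool:
    """Entrainer iff RVL >= cutoff (the cutoff itself is an entrainer)."""
    if not 0.0 <= rvl <= 1.0:
        raise ValueError(f"rvl must lie in [0, 1], got {rvl}")
    return rvl >= cutoff


def entrainment_summary(session: SessionRecord, config: RunConfig) -> EntrainmentSummary:
    """Full entrainment summary of one music session.

    Steps of both feet are pooled against the beat sequence (the music
    tempo is set in steps per minute, one beat per step). Steps outside
    the trimmed analysis window, or before the first / after the last
    beat, are excluded and counted in the log.
    """
    if not session.has_music:
        raise ValidationError(
            f"session {session.runner_id}/{session.condition} has no music; "
            "entrainment metrics are undefined (use kinematics only)"
        )
    steps: list[StepEvent] = trim_window(
        session.step_events, session.duration, config.trim_start, config.trim_end
    )
    st = np.array([e.t for e in steps])
    angles, n_dropped = relative_phases(st, session.beat_schedule)
    if n_dropped:
        logger.info(
            "%s/%s: %d steps outside the beat schedule excluded from rPA",
            session.runner_id, session.condition, n_dropped,
        )
    if angles.size == 0:
        raise UndefinedScoreError("no steps within the analysis window and beat schedule")

    rvl = resultant_vector_length(angles)
    is_entrainer = classify_entrainer(rvl, config.rvl_cutoff)
    mean_rpa = circular_mean(angles) if is_entrainer else None

    cad_t, cad_v = cadence_series(steps, window=config.cadence_window)
    te = tempo_entrainment(cad_t, cad_v, st, session.beat_schedule,
                           tolerance=config.tempo_tolerance)
    return EntrainmentSummary(
        tempo_entrainment=te,
        mean_rpa=mean_rpa,
        rvl=rvl,
        is_entrainer=is_entrainer,
        n_steps_analyzed=int(angles.size),
        raw_angles=angles,
    )
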
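"""Circular statistics for footfall-to-beat phase analysis.

A footfall at time St bracketed by beats B1 <= St < B2 has relative phase

    phi = 360 * (St - B1) / (B2 - B1)   degrees,

wrapped to (-180, 180] so that a footfall just *before* its nearest beat
carries a negative angle and the exact anti-phase point is +180. The
circular mean of a set of angles is the direction of their mean unit
vector, and the resultant vector length (RVL) is that vector's norm:
RVL = 1 for perfectly repeatable phase, RVL ~ 0 for no phase relation.
"""

from __future__ import annotations

import numpy as np

from .types import BeatSchedule, ValidationError


class UndefinedMeanError(ValueError):
    """The mean direction is undefined (zero resultant vector)."""


def wrap_degrees(angle):
    """Wrap angle(s) in degrees to the interval (-180, 180].

    The antipode is canonically +180: wrap_degrees(-180) == 180.
    """
    return 180.0 - (180.0 - np.asarray(angle, dtype=float)) % 360.0


def relative_phase(step_time: float, beats: BeatSchedule) -> float:
    """Relative phase angle (degrees) of one footfall within its beat interval.

    ``step_time`` must lie within [first beat, last beat]; a step exactly on
    a beat returns 0.0. Result is in (-180, 180].
    """
    times = beats.times
    if step_time < times[0] or step_time > times[-1]:
        raise ValidationError(
            f"step at {step_time} s lies outside the beat schedule "
            f"[{times[0]}, {times[-1]}]"
        )
    i = int(np.searchsorted(times, step_time, side="right")) - 1
    if i >= len(times) - 1:  # step exactly on the final beat
        return 0.0
    raw = 360.0 * (step_time - times[i]) / (times[i + 1] - times[i])
    # snap to nanodegree resolution: floating-point jitter at the exact
    # landmarks (on-beat, antipode) must not flip the wrap convention
    return float(wrap_degrees(round(raw, 9)))


def relative_phases(step_times: np.ndarray, beats: BeatSchedule) -> tuple[np.ndarray, int]:
    """Relative phases of many steps; steps outside the schedule are dropped.

    Returns (angles in degrees, number of dropped steps).
    """
    st = np.asarray(step_times, dtype=float)
    inside = (st >= beats.times[0]) & (st <= beats.times[-1])
    kept = st[inside]
    angles = np.array([relative_phase(t, beats) for t in kept])
    return angles, int(st.size - kept.size)


def _mean_vector(angles_deg: np.ndarray) -> tuple[float, float]:
    rad = np.deg2rad(np.asarray(angles_deg, dtype=float))
    return float(np.mean(np.cos(rad))), float(np.mean(np.sin(rad)))


def circular_mean(angles_deg) -> float:
    """Direction (degrees, in (-180, 180]) of the mean unit vector."""
    angles = np.asarray(angles_deg, dtype=float)
    if angles.size == 0:
        raise ValueError("circular_mean of an empty set is undefined")
    c, s = _mean_vector(angles)
    if np.hypot(c, s) < 1e-12:
        raise UndefinedMeanError("zero resultant vector: mean direction undefined")
    return float(wrap_degrees(np.rad2deg(np.arctan2(s, c))))


def resultant_vector_length(angles_deg) -> float:
    """Norm of the mean unit vector of the angles, in [0, 1]."""
    angles = np.asarray(angles_deg, dtype=float)
    if angles.size == 0:
        raise ValueError("resultant_vector_length of an empty set is undefined")
    c, s = _mean_vector(angles)
    return float(min(np.hypot(c, s), 1.0))
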
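"""Gait kinematics from ankle gyroscopes, heel prints, and a backpack sonar.

Three features of running are recovered here:

* **cadence** (steps per minute) — each reversal of leg angular velocity
  (a negative-to-positive zero crossing of the gyroscope signal) marks a
  step; cadence is a moving average over a window of consecutive same-leg
  steps (default 8 steps, i.e. 7 stride intervals).
* **step length** (m) — the along-track distance from one heel print to
  the next heel print of the opposite foot.
* **speed** (km/h) — the track carries marker rods at a known spacing; a
  sonar pointed at them shows a distance minimum at every passage, and
  speed is the rod spacing over the time between consecutive minima.
"""

from __future__ import annotations

import logging

import numpy as np

from .types import FEET, SensorTrace, StepEvent, ValidationError

logger = logging.getLogger(__name__)


def detect_steps(gyro: SensorTrace, min_interval: float = 0.4) -> np.ndarray:
    """Step times of one leg from its angular-velocity trace.

    A step is a negative-to-positive zero crossing (movement-direction
    reversal), located by linear interpolation between samples. Crossings
    within ``min_interval`` seconds of the previously accepted one are
    treated as noise and suppressed.
    """
    if min_interval <= 0:
        raise ValueError("min_interval must be > 0")
    gyro.check_uniform()
    t, v = gyro.times, gyro.values
    if len(gyro) < 2:
        return np.empty(0)
    up = np.flatnonzero((v[:-1] < 0) & (v[1:] >= 0))
    if up.size == 0:
        return np.empty(0)
    frac = -v[up] / (v[up + 1] - v[up])
    crossings = t[up] + frac * (t[up + 1] - t[up])
    accepted: list[float] = []
    for tc in crossings:
        if not accepted or tc - accepted[-1] >= min_interval:
            accepted.append(float(tc))
    return np.array(accepted)


def merge_feet(left: np.ndarray, right: np.ndarray,
               left_heel: np.ndarray | None = None,
               right_heel: np.ndarray | None = None) -> list[StepEvent]:
    """Merge per-foot step times into one time-sorted labeled sequence.

    Heel positions default to NaN when not supplied (gyro-only detection).
    Two consecutive same-foot steps with no opposite-foot step between them
    are legal but logged as a warning (a likely missed detection).
    """
    def _events(times, heels, foot):
        times = np.asarray(times, dtype=float)
        if heels is None:
            heels = np.full(times.shape, np.nan)
        return [StepEvent(float(t), foot, float(h)) for t, h in zip(times, heels)]

    merged = sorted(_events(left, left_heel, "left") + _events(right, right_heel, "right"),
                    key=lambda e: e.t)
    for prev, cur in zip(merged, merged[1:]):
        if prev.foot == cur.foot:
            logger.warning(
                "non-alternating feet: consecutive %s steps at %.3f s and %.3f s",
                cur.foot, prev.t, cur.t,
            )
    return merged


def cadence_series(events: list[StepEvent], window: int = 8) -> tuple[np.ndarray, np.ndarray]:
    """Moving-average cadence (SPM) from merged step events.

    Per foot, every run of ``window`` consecutive same-leg steps spans
    ``window - 1`` stride intervals; cadence there is ``2 * 60 / mean
    stride interval`` (two steps per stride), timestamped at the window's
    last step. The two feet's series are interleaved in time order.

    Returns ``(times, spm)``; empty arrays when no foot accumulates a full
    window.
    """
    if window < 2:
        raise ValueError("cadence window must be >= 2")
    out_t: list[np.ndarray] = []
    out_c: list[np.ndarray] = []
    for foot in FEET:
        ft = np.array([e.t for e in events if e.foot == foot])
        if ft.size < window:
            continue
        spans = ft[window - 1:] - ft[:-(window - 1)]
        mean_interval = spans / (window - 1)
        out_t.append(ft[window - 1:])
        out_c.append(120.0 / mean_interval)
    if not out_t:
        return np.empty(0), np.empty(0)
    times = np.concatenate(out_t)
    spm = np.concatenate(out_c)
    order = np.argsort(times, kind="stable")
    return times[order], spm[order]


def step_lengths(events: list[StepEvent], track_length: float = 289.0,
                 max_step: float = 3.0) -> np.ndarray:
    """Heel-to-heel step lengths (m) from the merged event sequence.

    Heel positions are along-track coordinates on a circular track and may
    wrap at ``track_length``; a negative raw difference is corrected by one
    lap. A length non-positive or beyond ``max_step`` after wrap
    correction (a backwards jump masquerading as a wrap) indicates corrupt
    input.
    """
    if len(events) < 2:
        return np.empty(0)
    x = np.array([e.heel_x for e in events], dtype=float)
    d = np.diff(x)
    d[d <= 0] += track_length
    bad = (d <= 0) | (d > max_step)
    if np.any(bad):
        i = int(np.flatnonzero(bad)[0])
        raise ValidationError(
            f"implausible step length {d[i]:.3f} m after wrap correction at step {i + 1}"
        )
    return d


def detect_rod_passages(sonar: SensorTrace, dip_threshold: float = 3.0,
                        min_gap: float = 1.0) -> np.ndarray:
    """Times of sonar distance minima marking passages along marker rods.

    Each excursion of the distance signal below ``dip_threshold``
    contributes the time of its minimum sample; minima closer than
    ``min_gap`` seconds are merged (deepest wins).
    """
    t, v = sonar.times, sonar.values
    below = v < dip_threshold
    if not below.any():
        return np.empty(0)
    # excursion boundaries
    edges = np.diff(below.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if below[0]:
        starts.insert(0, 0)
    if below[-1]:
        ends.append(len(v))
    minima = []
    for s, e in zip(starts, ends):
        i = s + int(np.argmin(v[s:e]))
        minima.append((t[i], v[i]))
    merged: list[tuple[float, float]] = []
    for tm, vm in minima:
        if merged and tm - merged[-1][0] < min_gap:
            if vm < merged[-1][1]:
                merged[-1] = (tm, vm)
        else:
            merged.append((tm, vm))
    return np.array([tm for tm, _ in merged])


def speed_series(passages: np.ndarray, rod_spacing: float = 9.97) -> tuple[np.ndarray, np.ndarray]:
    """Average speed (km/h) between consecutive rod passages.

    Returns ``(interval midpoint times, speeds)``; each speed is
    ``3.6 * rod_spacing / interval``. Fewer than two passages yield empty
    output.
    """
    p = np.asarray(passages, dtype=float)
    if p.size < 2:
        return np.empty(0), np.empty(0)
    dt = np.diff(p)
    if np.any(dt <= 0):
        raise ValidationError("passage times must be strictly increasing")
    return (p[:-1] + p[1:]) / 2.0, 3.6 * rod_spacing / dt
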
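"""The experimental protocol: condition order and the adaptive music tempo.

Each runner completes, in order: a training run (warm-up), a silent
``no_music`` run, a familiarization listening task, an ``uninstructed``
music run, an ``instructed`` music run, and a final control run. Only
``no_music``, ``uninstructed`` and ``instructed`` enter the analysis.

The music tempo for both music conditions is set per runner to the
cadence measured over the last 120 steps of the silent run, so the
stimulus starts period-matched to the runner's self-paced tempo. The
track's original tempo is 168 BPM; the tempo manipulation stretches it
to the target BPM, which must stay within the recreational running range
of 130-200 steps per minute.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .simulate import RunnerSpec, simulate_session
from .types import BeatSchedule, SessionRecord, StepEvent

#: Full protocol order; only ANALYZED conditions produce analyzed data.
PROTOCOL_ORDER = ("training", "no_music", "familiarization",
                  "uninstructed", "instructed", "control")

ORIGINAL_BPM = 168.0
SPM_BOUNDS = (130.0, 200.0)


class ProtocolError(ValueError):
    """A protocol rule cannot be satisfied by the data at hand."""


@dataclass
class ProtocolPlan:
    """Per-runner protocol manifest: condition order and music tempi."""

    runner_id: str
    order: tuple[str, ...] = PROTOCOL_ORDER
    music_bpm: dict[str, float] = field(default_factory=dict)  # condition -> BPM


def adaptive_tempo(no_music_events: list[StepEvent], n_last: int = 120) -> float:
    """Music tempo (BPM) matching the cadence of the final ``n_last`` steps.

    Computed as the mean step rate over the final ``n_last`` inter-step
    intervals (both feet pooled), unrounded:
    ``BPM = 60 * n_last / (t_last - t_{last - n_last})``.
    """
    times = np.sort(np.array([e.t for e in no_music_events], dtype=float))
    if times.size < n_last + 1:
        raise ProtocolError(
            f"adaptive tempo needs at least {n_last + 1} steps, got {times.size} "
            f"({n_last + 1 - times.size} short)"
        )
    span = times[-1] - times[-1 - n_last]
    if span <= 0:
        raise ProtocolError("degenerate step timing: zero span over the adaptation window")
    return 60.0 * n_last / span


def build_beat_schedule(bpm: float, duration: float,
                        original_bpm: float = ORIGINAL_BPM,
                        spm_bounds: tuple[float, float] = SPM_BOUNDS) -> BeatSchedule:
    """Isochronous beat schedule at ``bpm`` covering [0, duration].

    The implied stretch factor ``bpm / original_bpm`` is recorded on the
    schedule and must lie in (0, 2], the range the tempo-stretching tool
    supports; ``bpm`` must lie within the recreational cadence bounds.
    """
    lo, hi = spm_bounds
    if not lo <= bpm <= hi:
        raise ProtocolError(f"music tempo {bpm:.2f} BPM outside supported range [{lo}, {hi}]")
    stretch = bpm / original_bpm
    if not 0.0 < stretch <= 2.0:
        raise ProtocolError(f"stretch factor {stretch:.3f} outside (0, 2]")
    n = int(np.floor(duration * bpm / 60.0)) + 1
    times = np.arange(n) * 60.0 / bpm
    return BeatSchedule(times=times, bpm=np.full(n, float(bpm)),
                        stretch_factor=float(stretch))


def run_protocol(cohort: list[RunnerSpec], config: RunConfig,
                 seed: int | np.random.Generator,
                 ) -> tuple[dict[str, dict[str, SessionRecord]], list[ProtocolPlan]]:
    """Simulate the analyzed protocol for a whole cohort.

    For each runner: simulate the silent run, derive the adaptive tempo
    from its last ``config.adaptation_steps`` steps, build one beat
    schedule, and reuse it for both the uninstructed and the instructed
    session ("the same stimulus"). Returns ``(sessions, plans)`` where
    ``sessions[runner_id][condition]`` holds the three analyzed sessions.
    """
    if not cohort:
        raise ValueError("cohort must be nonempty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sessions: dict[str, dict[str, SessionRecord]] = {}
    plans: list[ProtocolPlan] = []
    for runner in cohort:
        try:
            silent = simulate_session(runner, "no_music", None, config, rng)
            bpm = adaptive_tempo(silent.step_events, config.adaptation_steps)
            beats = build_beat_schedule(bpm, config.session_duration)
            uninstructed = simulate_session(runner, "uninstructed", beats, config, rng)
            instructed = simulate_session(runner, "instructed", beats, config, rng)
        except Exception as exc:
            raise ProtocolError(f"runner {runner.runner_id}: {exc}") from exc
        sessions[runner.runner_id] = {
            "no_music": silent, "uninstructed": uninstructed, "instructed": instructed,
        }
        plans.append(ProtocolPlan(
            runner_id=runner.runner_id,
            music_bpm={"uninstructed": bpm, "instructed": bpm},
        ))
    return sessions, plans
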
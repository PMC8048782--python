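"""Synthetic cohorts of recreational runners and their sensor recordings.

The generator emulates the statistical structure the analysis assumes:

* runners with a stable individual cadence (steps per minute, SPM) and
  step length, with females running at higher cadence and shorter steps
  than males;
* per-condition shifts of cadence and step length (music slightly raises
  cadence; an instruction to entrain shortens steps relative to
  uninstructed running);
* phase-coupled footfalls for entrainers — one step per musical beat,
  with a von Mises-distributed phase offset of mean ``mu`` (negative:
  footfall ahead of the beat) and concentration ``kappa``, so the
  expected resultant vector length is the Bessel ratio I1(kappa)/I0(kappa);
* uncoupled (renewal) footfalls for nonentrainers, at the runner's own
  tempo with normal short-term jitter, independent of the music;
* gyroscope-like 100 Hz traces whose negative-to-positive zero crossings
  occur at the step times, and a 250 Hz sonar distance trace dipping at
  marker rods spaced 9.97 m along a 289 m circular track.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .types import (
    ANALYZED_CONDITIONS,
    MUSIC_CONDITIONS,
    BeatSchedule,
    SensorTrace,
    SessionRecord,
    StepEvent,
    ValidationError,
)

#: Per-condition additive shifts (cadence SPM, step length m) relative to
#: silent running, taken from typical recreational-running group means.
CADENCE_DELTAS = {"no_music": 0.0, "uninstructed": 2.11, "instructed": 1.52}
STEP_LENGTH_DELTAS = {"no_music": 0.0, "uninstructed": 0.03, "instructed": -0.01}

#: Default fraction of entrainers per music condition: about one third of
#: runners entrain spontaneously, while an explicit instruction raises the
#: fraction to a small majority.
ENTRAINER_PROBS = {"uninstructed": 1.0 / 3.0, "instructed": 0.58}

MUSIC_HABITS = ("without", "with", "both")
MUSIC_HABIT_PROBS = (0.5152, 0.3939, 0.0909)

_KAPPA_CAP = 1e6


@dataclass
class RunnerSpec:
    """Generative parameters of one virtual runner."""

    runner_id: str
    sex: str  # "male" | "female"
    baseline_cadence: float       # SPM, silent self-paced running
    baseline_step_length: float   # m
    condition_effects: dict[str, tuple[float, float]]  # cond -> (d_spm, d_len_m)
    entrainer_flags: dict[str, bool]  # per music condition
    phase_offset_mu: float        # degrees; negative = footfall before the beat
    phase_concentration_kappa: float
    cadence_sd: float             # SPM, short-term step-to-step variability
    step_length_sd: float = 0.02  # m
    musically_trained: bool = False
    music_habit: str = "without"

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValidationError(f"unknown sex {self.sex!r}")
        if not 130.0 <= self.baseline_cadence <= 200.0:
            raise ValidationError("baseline_cadence must lie in [130, 200] SPM")
        if self.baseline_step_length <= 0:
            raise ValidationError("baseline_step_length must be > 0")
        if self.phase_concentration_kappa < 0:
            raise ValidationError("phase_concentration_kappa must be >= 0")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def make_cohort(
    n: int,
    config: RunConfig | None = None,
    seed: int | np.random.Generator = 0,
    *,
    cadence_mean: float = 169.0,
    cadence_between_sd: float = 8.0,
    sex_cadence_gap: float = 7.4,
    step_length_means: tuple[float, float] = (1.21, 1.00),  # (male, female)
    step_length_between_sd: float = 0.12,
    entrainer_probs: dict[str, float] | None = None,
    trained_entrain_boost: float = 2.0,
    trained_prob: float = 0.3636,
    phase_mu_mean: float = -40.0,
    phase_mu_sd: float = 15.0,
    kappa_range: tuple[float, float] = (4.0, 8.0),
    cadence_sd_range: tuple[float, float] = (1.0, 2.0),
) -> list[RunnerSpec]:
    """Draw ``n`` virtual runners, deterministic given ``seed``.

    Sexes are balanced to within one runner (females take the extra slot).
    Baseline cadences are normal around ``cadence_mean`` with a
    female-minus-male gap of ``sex_cadence_gap`` SPM, truncated to the
    recreational range [130, 200]. Entrainer flags are Bernoulli per music
    condition with the stated marginal probabilities; musically trained
    runners carry ``trained_entrain_boost``-fold relative odds of
    entraining, with the marginal preserved.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    rng = _rng(seed)
    probs = dict(ENTRAINER_PROBS if entrainer_probs is None else entrainer_probs)

    specs: list[RunnerSpec] = []
    for i in range(n):
        sex = "female" if i % 2 == 0 else "male"  # (n+1)//2 females
        trained = bool(rng.random() < trained_prob)
        habit = MUSIC_HABITS[rng.choice(len(MUSIC_HABITS), p=np.array(MUSIC_HABIT_PROBS) /
                                        sum(MUSIC_HABIT_PROBS))]
        half = sex_cadence_gap / 2.0
        cad_mu = cadence_mean + (half if sex == "female" else -half)
        cadence = float(np.clip(rng.normal(cad_mu, cadence_between_sd), 130.0, 200.0))
        slen_mu = step_length_means[0] if sex == "male" else step_length_means[1]
        slen = float(max(rng.normal(slen_mu, step_length_between_sd), 0.5))
        effects = {
            cond: (
                CADENCE_DELTAS[cond] + (rng.normal(0.0, 0.8) if cond != "no_music" else 0.0),
                STEP_LENGTH_DELTAS[cond] + (rng.normal(0.0, 0.015) if cond != "no_music" else 0.0),
            )
            for cond in ANALYZED_CONDITIONS
        }
        flags = {}
        for cond in MUSIC_CONDITIONS:
            p = probs[cond]
            # odds-style boost for trained runners, marginal preserved
            p_untrained = p / (trained_prob * trained_entrain_boost + (1.0 - trained_prob))
            p_cond = min(p_untrained * (trained_entrain_boost if trained else 1.0), 0.95)
            flags[cond] = bool(rng.random() < p_cond)
        specs.append(RunnerSpec(
            runner_id=f"r{i + 1:03d}",
            sex=sex,
            baseline_cadence=cadence,
            baseline_step_length=slen,
            condition_effects=effects,
            entrainer_flags=flags,
            phase_offset_mu=float(rng.normal(phase_mu_mean, phase_mu_sd)),
            phase_concentration_kappa=float(rng.uniform(*kappa_range)),
            cadence_sd=float(rng.uniform(*cadence_sd_range)),
            musically_trained=trained,
            music_habit=habit,
        ))
    return specs


def phase_coupled_steps(beats: BeatSchedule, mu: float, kappa: float,
                        n_steps: int, seed) -> np.ndarray:
    """Step times phase-locked to a beat schedule, one step per beat.

    Step ``k`` is beat ``k`` shifted by ``phi_k / 360`` of the local
    inter-beat interval, with ``phi_k ~ von Mises(mu, kappa)`` in degrees
    wrapped to (-180, 180]. ``kappa = 0`` gives uniformly random phase.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if n_steps > len(beats):
        raise ValueError(f"requested {n_steps} steps but schedule has {len(beats)} beats")
    rng = _rng(seed)
    phi = np.rad2deg(rng.vonmises(np.deg2rad(mu), min(kappa, _KAPPA_CAP), size=n_steps))
    if len(beats) > 1:
        ibi = np.diff(beats.times)
        local = np.append(ibi, ibi[-1])[:n_steps]
    else:
        local = np.full(n_steps, 60.0 / float(beats.bpm[0]))
    return beats.times[:n_steps] + phi / 360.0 * local


def _renewal_steps(cadence: float, cadence_sd: float, duration: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Uncoupled step times: a renewal process at the runner's own tempo."""
    if cadence <= 0:
        raise ValueError("cadence must be > 0")
    n_max = int(duration * (cadence + 6.0 * max(cadence_sd, 1.0)) / 60.0) + 10
    tempi = np.clip(cadence + rng.normal(0.0, cadence_sd, size=n_max), 30.0, None)
    intervals = 60.0 / tempi
    t0 = rng.uniform(0.0, 60.0 / cadence)
    times = t0 + np.concatenate([[0.0], np.cumsum(intervals[:-1])])
    return times[times <= duration]


def synth_gyro_trace(step_times_one_leg, config: RunConfig, seed,
                     duration: float | None = None) -> SensorTrace:
    """Angular-velocity-like trace for one leg.

    One sine cycle per stride, phased so that every negative-to-positive
    zero crossing falls on a step time; outside the stepping interval the
    signal is held clear of zero so no spurious crossings arise. Additive
    Gaussian noise of sd ``config.gyro_noise_sd`` (amplitude is 1).
    """
    rng = _rng(seed)
    duration = config.session_duration if duration is None else duration
    t = np.arange(0.0, duration, 1.0 / config.gyro_rate)
    s = np.sort(np.asarray(step_times_one_leg, dtype=float))
    if s.size == 0:
        values = np.zeros_like(t)
    else:
        if s.size == 1:
            f = (t - s[0]) / 0.7
        else:
            f = np.interp(t, s, np.arange(s.size, dtype=float))
            first, last = s[0], s[-1]
            t_first = s[1] - s[0]
            t_last = s[-1] - s[-2]
            f = np.where(t < first, (t - first) / t_first, f)
            f = np.where(t > last, (s.size - 1) + (t - last) / t_last, f)
        f = np.clip(f, -0.25, (s.size - 1) + 0.25)
        values = np.sin(2.0 * np.pi * f)
    if config.gyro_noise_sd > 0:
        values = values + rng.normal(0.0, config.gyro_noise_sd, size=values.size)
    return SensorTrace(t, values)


def synth_sonar_trace(profile_times, profile_kmh, config: RunConfig, seed) -> SensorTrace:
    """Sonar distance trace with a V-shaped dip at every marker-rod passage.

    The speed profile (km/h over time) is integrated to along-track
    position; each crossing of a rod position (multiples of
    ``config.rod_spacing``, wrapping every lap of ``config.track_length``)
    produces a dip from the far plateau to the near distance.
    """
    pt = np.asarray(profile_times, dtype=float)
    pv = np.asarray(profile_kmh, dtype=float)
    if pt.size == 0:
        return SensorTrace(np.empty(0), np.empty(0))
    if np.any(pv <= 0):
        raise ValueError("speed profile must be strictly positive")
    t = np.arange(pt[0], pt[-1], 1.0 / config.sonar_rate)
    if t.size < 2:
        return SensorTrace(t, np.full(t.shape, config.sonar_far))
    v_ms = np.interp(t, pt, pv) / 3.6
    dt = np.diff(t)
    pos = np.concatenate([[0.0], np.cumsum((v_ms[1:] + v_ms[:-1]) / 2.0 * dt)])

    # rod positions in unwrapped coordinates: j * spacing within each lap
    rods_one_lap = np.arange(config.n_rods) * config.rod_spacing
    rods_one_lap = rods_one_lap[rods_one_lap < config.track_length]
    n_laps = int(pos[-1] // config.track_length) + 1
    rods = (rods_one_lap[None, :] + np.arange(n_laps)[:, None] * config.track_length).ravel()
    rods = rods[(rods > 0) & (rods < pos[-1])]
    crossing_times = np.interp(rods, pos, t)

    values = np.full(t.shape, config.sonar_far)
    hw = config.sonar_dip_halfwidth
    for tc in crossing_times:
        i0, i1 = np.searchsorted(t, [tc - hw, tc + hw])
        seg = t[i0:i1]
        dip = config.sonar_near + (config.sonar_far - config.sonar_near) * np.abs(seg - tc) / hw
        values[i0:i1] = np.minimum(values[i0:i1], dip)
    rng = _rng(seed)
    if config.sonar_noise_sd > 0:
        values = values + rng.normal(0.0, config.sonar_noise_sd, size=values.size)
    return SensorTrace(t, np.clip(values, 0.0, None))


def simulate_session(runner: RunnerSpec, condition: str,
                     beats: BeatSchedule | None, config: RunConfig,
                     seed) -> SessionRecord:
    """One 4-minute session of one runner under one condition.

    Entrained music sessions take their step times from
    :func:`phase_coupled_steps`; all other sessions follow a renewal
    process at the runner's condition-adjusted cadence. Feet alternate
    starting with the right foot; heel positions advance by per-step
    lengths and wrap at the track length.
    """
    if condition not in ANALYZED_CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if (beats is not None) != (condition in MUSIC_CONDITIONS):
        raise ValueError("a beat schedule is required exactly for music conditions")
    rng = _rng(seed)
    duration = config.session_duration
    d_spm, d_len = runner.condition_effects.get(condition, (0.0, 0.0))
    cadence = runner.baseline_cadence + d_spm
    slen = max(runner.baseline_step_length + d_len, 0.2)

    entrained = condition in MUSIC_CONDITIONS and runner.entrainer_flags.get(condition, False)
    if entrained:
        times = phase_coupled_steps(beats, runner.phase_offset_mu,
                                    runner.phase_concentration_kappa, len(beats), rng)
        times = np.sort(times[(times >= 0.0) & (times <= duration)])
    else:
        times = _renewal_steps(cadence, runner.cadence_sd, duration, rng)

    lengths = np.clip(slen + rng.normal(0.0, runner.step_length_sd, size=times.size),
                      0.1, None)
    heel = np.cumsum(lengths) % config.track_length
    feet = np.where(np.arange(times.size) % 2 == 0, "right", "left")
    events = [StepEvent(float(t), str(f), float(x)) for t, f, x in zip(times, feet, heel)]

    # ground-truth speed: cadence/60 * step length, pointwise, in km/h
    prof_t = np.arange(0.0, duration + 1e-9, 0.1)
    cad_t = np.asarray(beats.bpm_at(prof_t), dtype=float) if entrained \
        else np.full(prof_t.shape, cadence)
    prof_v = 3.6 * (cad_t / 60.0) * slen

    gyro = {
        foot: synth_gyro_trace(times[feet == foot], config, rng, duration=duration)
        for foot in ("left", "right")
    }
    sonar = synth_sonar_trace(prof_t, prof_v, config, rng)
    return SessionRecord(
        runner_id=runner.runner_id,
        condition=condition,
        duration=duration,
        step_events=events,
        beat_schedule=beats,
        gyro_left=gyro["left"],
        gyro_right=gyro["right"],
        sonar=sonar,
        true_speed_profile=(prof_t, prof_v),
    )
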
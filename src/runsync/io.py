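"""Readers and writers for the pipeline's on-disk formats.

All files are plain CSV (comma-separated, "." decimal, UTF-8, mandatory
header row). Times are seconds from session start.

* step events:   session_id, condition, foot, t_s, heel_x_m
* beat schedule: t_s, bpm
* sensor trace:  t_s, value
* cohort:        runner_id, sex, musically_trained, music_habit
* features:      runner_id, condition, cadence_spm, step_length_m,
                 speed_kmh, tempo_entrainment_pct, mean_rpa_deg (empty
                 when the RVL gate withholds it), rvl, is_entrainer,
                 n_steps_analyzed
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import RunnerSpec
from .types import BeatSchedule, SensorTrace, StepEvent, ValidationError

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6f"


class FormatError(ValueError):
    """A file does not follow its expected tabular format."""


def _read_csv(path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing input file: {path}")
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


# ---------------------------------------------------------------------------
# step events

def read_step_events(path) -> list[StepEvent]:
    """Read a step-event CSV, validated and sorted by time.

    Times must be nonnegative and nondecreasing within each
    (session_id, foot) group; foot labels are "left"/"right".
    """
    df = _read_csv(path, ("session_id", "condition", "foot", "t_s", "heel_x_m"))
    if len(df) == 0:
        return []
    bad_feet = ~df["foot"].isin(("left", "right"))
    if bad_feet.any():
        i = int(df.index[bad_feet][0])
        raise ValidationError(f"{path}: unknown foot label {df['foot'][i]!r} at row {i}")
    if (df["t_s"] < 0).any():
        i = int(df.index[df["t_s"] < 0][0])
        raise ValidationError(f"{path}: negative time at row {i}")
    for (sid, foot), grp in df.groupby(["session_id", "foot"]):
        t = grp["t_s"].to_numpy(float)
        if np.any(np.diff(t) < 0):
            row = int(grp.index[np.flatnonzero(np.diff(t) < 0)[0] + 1])
            raise ValidationError(
                f"{path}: non-monotone time for session {sid!r} foot {foot!r} at row {row}"
            )
    df = df.sort_values("t_s", kind="stable")
    return [StepEvent(float(r.t_s), str(r.foot), float(r.heel_x_m))
            for r in df.itertuples()]


def write_step_events(events: list[StepEvent], path, session_id: str,
                      condition: str) -> None:
    df = pd.DataFrame({
        "session_id": session_id,
        "condition": condition,
        "foot": [e.foot for e in events],
        "t_s": [e.t for e in events],
        "heel_x_m": [e.heel_x for e in events],
    })
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# beat schedules

def read_beat_schedule(path) -> BeatSchedule:
    """Read a beat-schedule CSV (strictly increasing t_s, positive bpm).

    Inter-beat intervals inconsistent with the stated bpm by more than
    1 % are tolerated but logged as a warning.
    """
    df = _read_csv(path, ("t_s", "bpm"))
    t = df["t_s"].to_numpy(float)
    bpm = df["bpm"].to_numpy(float)
    schedule = BeatSchedule(times=t, bpm=bpm)  # validates monotonicity, bpm > 0
    if len(t) > 1:
        implied = 60.0 / np.diff(t)
        stated = bpm[:-1]
        rel = np.abs(implied - stated) / stated
        if np.any(rel > 0.01):
            k = int(np.argmax(rel))
            logger.warning(
                "%s: inter-beat interval at beat %d implies %.2f BPM vs stated %.2f",
                path, k, implied[k], stated[k],
            )
    return schedule


def write_beat_schedule(schedule: BeatSchedule, path) -> None:
    pd.DataFrame({"t_s": schedule.times, "bpm": schedule.bpm}).to_csv(
        path, index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# sensor traces

def read_trace(path) -> SensorTrace:
    df = _read_csv(path, ("t_s", "value"))
    return SensorTrace(df["t_s"].to_numpy(float), df["value"].to_numpy(float))


def write_trace(trace: SensorTrace, path) -> None:
    pd.DataFrame({"t_s": trace.times, "value": trace.values}).to_csv(
        path, index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# cohort and feature tables

def write_cohort(cohort: list[RunnerSpec], path) -> None:
    pd.DataFrame({
        "runner_id": [r.runner_id for r in cohort],
        "sex": [r.sex for r in cohort],
        "musically_trained": [r.musically_trained for r in cohort],
        "music_habit": [r.music_habit for r in cohort],
    }).to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = _read_csv(path, ("runner_id", "sex", "musically_trained", "music_habit"))
    df["musically_trained"] = df["musically_trained"].astype(bool)
    return df


_FEATURE_COLS = {
    "cadence": "cadence_spm",
    "step_length": "step_length_m",
    "speed": "speed_kmh",
    "tempo_entrainment": "tempo_entrainment_pct",
    "mean_rpa": "mean_rpa_deg",
    "rvl": "rvl",
    "is_entrainer": "is_entrainer",
    "n_steps": "n_steps_analyzed",
}


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write the per-session feature table with its on-disk column names."""
    out = table.rename(columns=_FEATURE_COLS)
    cols = ["runner_id", "condition"] + [c for c in _FEATURE_COLS.values()
                                         if c in out.columns]
    out[cols].to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_feature_table(path) -> pd.DataFrame:
    df = _read_csv(path, ("runner_id", "condition"))
    inverse = {v: k for k, v in _FEATURE_COLS.items()}
    return df.rename(columns=inverse)
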
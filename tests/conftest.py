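import numpy as np
import pytest

from runsync import RunConfig, RunnerSpec


@pytest.fixture
def config() -> RunConfig:
    return RunConfig()


@pytest.fixture
def quiet_config() -> RunConfig:
    """Standard protocol constants with all sensor noise switched off."""
    return RunConfig(gyro_noise_sd=0.0, sonar_noise_sd=0.0)


def make_runner(
    runner_id: str = "r001",
    sex: str = "male",
    cadence: float = 170.0,
    step_length: float = 1.12,
    entrainer: dict | None = None,
    mu: float = -34.0,
    kappa: float = 6.0,
    cadence_sd: float = 1.5,
    step_length_sd: float = 0.02,
    deltas: dict | None = None,
) -> RunnerSpec:
    """A runner spec with explicit, test-controlled parameters."""
    deltas = deltas if deltas is not None else {
        "no_music": (0.0, 0.0), "uninstructed": (2.11, 0.03), "instructed": (1.52, -0.01),
    }
    return RunnerSpec(
        runner_id=runner_id,
        sex=sex,
        baseline_cadence=cadence,
        baseline_step_length=step_length,
        condition_effects=deltas,
        entrainer_flags=entrainer or {"uninstructed": False, "instructed": False},
        phase_offset_mu=mu,
        phase_concentration_kappa=kappa,
        cadence_sd=cadence_sd,
        step_length_sd=step_length_sd,
    )


@pytest.fixture
def steady_beats():
    """Isochronous 168-BPM schedule covering 4 minutes."""
    from runsync import build_beat_schedule

    return build_beat_schedule(168.0, 240.0)


def circ_diff(a: float, b: float) -> float:
    """Smallest signed angular difference a - b in degrees."""
    return float((a - b + 180.0) % 360.0 - 180.0)


@pytest.fixture(scope="session")
def short_config_path(tmp_path_factory):
    """A 2-minute-session configuration file (fast pipeline runs)."""
    cfg = RunConfig(session_duration=120.0)
    path = tmp_path_factory.mktemp("cfg") / "config.yml"
    cfg.to_file(path)
    return path


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory, short_config_path):
    """A small simulated study written by the CLI simulate+detect stages."""
    from click.testing import CliRunner

    from runsync.cli import main

    out = tmp_path_factory.mktemp("study")
    runner = CliRunner()
    res = runner.invoke(main, ["simulate", "--config", str(short_config_path),
                               "--out", str(out), "--seed", "1", "--n", "4"])
    assert res.exit_code == 0, res.output
    res = runner.invoke(main, ["detect", "--config", str(short_config_path),
                               "--out", str(out)])
    assert res.exit_code == 0, res.output
    return out
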
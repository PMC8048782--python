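"""Study-level model object tying the pipeline together.

``EntrainmentStudy`` holds a dataset of running sessions (real or
simulated) together with runner covariates and the run configuration;
``fit()`` executes the full analysis — step detection, kinematics,
entrainment metrics, and the condition-level statistics — and returns an
``EntrainmentStudyResults`` carrying the per-session feature table, the
effect reports with their uncertainties, and a printable summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from . import stats as rstats
from .config import RunConfig
from .protocol import ProtocolPlan, run_protocol
from .simulate import RunnerSpec, make_cohort
from .types import ANALYZED_CONDITIONS, SessionRecord

logger = logging.getLogger(__name__)


class EntrainmentStudy:
    """A running-to-music entrainment study ready to be analyzed.

    Parameters
    ----------
    sessions
        ``{runner_id: {condition: SessionRecord}}`` for the analyzed
        conditions (no_music, uninstructed, instructed).
    cohort_info
        DataFrame with runner_id, sex, musically_trained, music_habit.
    config
        Protocol constants; defaults to the standard protocol.
    """

    def __init__(self, sessions: dict[str, dict[str, SessionRecord]],
                 cohort_info: pd.DataFrame, config: RunConfig | None = None):
        self.sessions = sessions
        self.cohort_info = cohort_info.reset_index(drop=True)
        self.config = config or RunConfig()
        self.plans: list[ProtocolPlan] = []

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_simulation(cls, n_runners: int = 33, config: RunConfig | None = None,
                        seed: int = 0, **cohort_kwargs) -> "EntrainmentStudy":
        """Simulate a full cohort through the experimental protocol."""
        config = config or RunConfig()
        rng = np.random.default_rng(seed)
        cohort = make_cohort(n_runners, config, rng, **cohort_kwargs)
        sessions, plans = run_protocol(cohort, config, rng)
        study = cls(sessions, _cohort_frame(cohort), config)
        study.plans = plans
        return study

    @classmethod
    def from_directory(cls, path, config: RunConfig | None = None) -> "EntrainmentStudy":
        """Load a study from a directory written by the ``simulate`` stage."""
        from .cli import load_sessions  # thin reuse of the CLI's layout

        path = Path(path)
        config = config or RunConfig()
        cohort_info = rio.read_cohort(path / "cohort.csv")
        sessions = load_sessions(path, config)
        return cls(sessions, cohort_info, config)

    # -- estimation ---------------------------------------------------------

    def fit(self, use_detection: bool = True) -> "EntrainmentStudyResults":
        """Run the full analysis and return the results object.

        With ``use_detection`` (default) step timing is re-derived from
        the gyroscope traces, exercising the deployed event-detection
        path; otherwise the provided step-event tables are used directly.
        """
        table = rstats.build_feature_table(self.sessions, self.cohort_info,
                                           self.config, use_detection)
        effects: dict[str, list[rstats.EffectReport]] = {}
        notes: dict[str, str] = {}
        for feature in rstats.FEATURES:
            try:
                effects[feature] = rstats.mixed_design_anova(table, feature)
            except rstats.InsufficientDataError as exc:
                notes[feature] = str(exc)
        try:
            subgroups = rstats.subgroup_tests(table)
        except rstats.InsufficientDataError as exc:
            subgroups = {}
            notes["subgroups"] = str(exc)
        return EntrainmentStudyResults(
            model=self, feature_table=table, effects=effects,
            subgroups=subgroups, notes=notes,
        )


@dataclass
class EntrainmentStudyResults:
    """Fitted study: feature table, effect reports, and summaries."""

    model: EntrainmentStudy
    feature_table: pd.DataFrame
    effects: dict[str, list[rstats.EffectReport]]
    subgroups: dict[str, list[rstats.EffectReport]]
    notes: dict[str, str] = field(default_factory=dict)

    def condition_summary(self, feature: str) -> pd.DataFrame:
        return rstats.condition_summary(self.feature_table, feature)

    def condition_means(self, feature: str) -> pd.Series:
        """Per-condition means of a feature over non-missing sessions."""
        return (self.feature_table.groupby("condition", observed=True)[feature]
                .mean().reindex([c for c in ANALYZED_CONDITIONS
                                 if c in set(self.feature_table["condition"])]))

    def entrainer_fraction(self, condition: str) -> float:
        sub = self.feature_table[self.feature_table["condition"] == condition]
        flags = sub["is_entrainer"].dropna().astype(bool)
        if flags.empty:
            raise ValueError(f"no entrainer flags for condition {condition!r}")
        return float(flags.mean())

    def summary(self) -> str:
        """Human-readable report of descriptives and effects."""
        lines = [
            "Running-to-music entrainment study",
            f"  runners: {self.feature_table['runner_id'].nunique()}, "
            f"sessions: {len(self.feature_table)}",
            "",
            "Condition means (mean +/- SE):",
        ]
        for feature in rstats.FEATURES:
            if feature not in self.feature_table.columns:
                continue
            cs = self.condition_summary(feature)
            cells = []
            for cond in ANALYZED_CONDITIONS:
                sub = cs[cs["condition"] == cond]
                if sub.empty or sub["mean"].isna().all():
                    continue
                pooled = self.feature_table[self.feature_table["condition"] == cond][feature]
                pooled = pooled.dropna()
                if pooled.empty:
                    continue
                se = pooled.std(ddof=1) / np.sqrt(len(pooled)) if len(pooled) > 1 else 0.0
                cells.append(f"{cond} {pooled.mean():.2f}+/-{se:.2f}")
            lines.append(f"  {feature:18s} " + "; ".join(cells))
        lines.append("")
        lines.append("Effects (mixed-design ANOVA, condition within / sex between):")
        for feature, reports in self.effects.items():
            lines.append(f"  {feature}:")
            for r in reports:
                lines.append(f"    {r.format()}")
        if self.subgroups:
            lines.append("Subgroup tests:")
            for feature, reports in self.subgroups.items():
                for r in reports:
                    lines.append(f"  {r.format()}")
        for key, note in self.notes.items():
            lines.append(f"  [{key}] not estimated: {note}")
        return "\n".join(lines)

    def plot_condition_means(self, feature: str, ax=None):
        """Mean +/- SE of a feature per condition and sex (matplotlib)."""
        import matplotlib.pyplot as plt

        cs = self.condition_summary(feature)
        if ax is None:
            _, ax = plt.subplots()
        for sex, grp in cs.groupby("sex"):
            grp = grp.set_index("condition").reindex(
                [c for c in ANALYZED_CONDITIONS if c in set(cs["condition"])])
            ax.errorbar(grp.index, grp["mean"], yerr=grp["se"], label=str(sex),
                        marker="o", capsize=3)
        ax.set_ylabel(feature)
        ax.set_xlabel("condition")
        ax.legend()
        return ax


def _cohort_frame(cohort: list[RunnerSpec]) -> pd.DataFrame:
    return pd.DataFrame({
        "runner_id": [r.runner_id for r in cohort],
        "sex": [r.sex for r in cohort],
        "musically_trained": [r.musically_trained for r in cohort],
        "music_habit": [r.music_habit for r in cohort],
    })
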
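"""Condition-level study statistics on pipeline outputs.

The study design is a 3 x 2 mixed design: *condition* (no music,
uninstructed, instructed) within subjects, *sex* between subjects.
Features that require music (tempo entrainment, mean rPA, RVL) use the
two music conditions only. Mean rPA enters the analysis only for runners
whose RVL reaches the entrainer cutoff in every compared condition, so
its error degrees of freedom are typically much smaller than the
cohort's. Enjoyment/exertion ratings are ordinal and compared with
Friedman's ANOVA followed by Bonferroni-corrected Wilcoxon signed-rank
tests; subgroup questions (musical training, music-listening habit) use
a pooled-variance t-test and a one-way ANOVA.

Partial eta squared is reported for every F effect,
``SS_effect / (SS_effect + SS_error)``.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import RunConfig
from .entrainment import entrainment_summary, trim_window
from .kinematics import (
    cadence_series,
    detect_rod_passages,
    detect_steps,
    merge_feet,
    speed_series,
    step_lengths,
)
from .types import ANALYZED_CONDITIONS, MUSIC_CONDITIONS, SessionRecord

logger = logging.getLogger(__name__)

FEATURES = ("cadence", "step_length", "speed", "tempo_entrainment", "mean_rpa", "rvl")
MUSIC_ONLY_FEATURES = ("tempo_entrainment", "mean_rpa", "rvl")


class InsufficientDataError(ValueError):
    """Too few complete cases (or too small a subgroup) for the test."""


@dataclass
class EffectReport:
    """One reported effect: statistic, degrees of freedom, p, effect size."""

    effect: str
    statistic_name: str  # "F", "t", "chi2", "z"
    statistic: float
    df1: float
    df2: Optional[float]
    p: float
    eta2: Optional[float] = None  # partial eta squared for F effects

    def __post_init__(self) -> None:
        if self.statistic_name == "F" and self.statistic < -1e-12:
            raise ValueError("F statistic must be nonnegative")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p value must lie in [0, 1]")
        if self.eta2 is not None and not 0.0 <= self.eta2 <= 1.0 + 1e-12:
            raise ValueError("eta squared must lie in [0, 1]")

    def format(self) -> str:
        df = (f"({self.df1:g},{self.df2:g})" if self.df2 is not None
              else f"({self.df1:g})")
        s = f"{self.effect}: {self.statistic_name}{df} = {self.statistic:.2f}, P = {self.p:.3g}"
        if self.eta2 is not None:
            s += f", eta2 = {self.eta2:.3f}"
        return s


# ---------------------------------------------------------------------------
# feature extraction

def session_features(session: SessionRecord, config: RunConfig,
                     use_detection: bool = True,
                     timing_events: list | None = None) -> dict:
    """Kinematic and entrainment features of one session.

    Step *timing* comes from ``timing_events`` when given (e.g. a
    previously run detection stage), else from the gyroscope traces when
    present and ``use_detection`` is set, else from the provided
    step-event table. Step lengths always come from the heel positions of
    the event table, and speed from the sonar trace when present (else
    from the ground-truth profile).
    """
    import dataclasses

    if timing_events is None:
        if use_detection and session.gyro_left is not None and session.gyro_right is not None:
            lt = detect_steps(session.gyro_left)
            rt = detect_steps(session.gyro_right)
            timing_events = merge_feet(lt, rt)
        else:
            timing_events = session.step_events
    lo, hi = config.trim_start, session.duration - config.trim_end
    trimmed_timing = trim_window(timing_events, session.duration,
                                 config.trim_start, config.trim_end)
    cad_t, cad_v = cadence_series(trimmed_timing, window=config.cadence_window)
    cadence = float(np.mean(cad_v)) if cad_v.size else np.nan

    trimmed_events = trim_window(session.step_events, session.duration,
                                 config.trim_start, config.trim_end)
    lengths = step_lengths(trimmed_events, track_length=config.track_length)
    step_length = float(np.mean(lengths)) if lengths.size else np.nan

    if session.sonar is not None and len(session.sonar) > 1:
        passages = detect_rod_passages(session.sonar)
        mid, spd = speed_series(passages, rod_spacing=config.rod_spacing)
        keep = (mid >= lo) & (mid <= hi)
        speed = float(np.mean(spd[keep])) if keep.any() else np.nan
    elif session.true_speed_profile is not None:
        pt, pv = session.true_speed_profile
        keep = (pt >= lo) & (pt <= hi)
        speed = float(np.mean(pv[keep]))
    else:
        speed = np.nan

    row = {
        "runner_id": session.runner_id,
        "condition": session.condition,
        "cadence": cadence,
        "step_length": step_length,
        "speed": speed,
        "tempo_entrainment": np.nan,
        "mean_rpa": np.nan,
        "rvl": np.nan,
        "is_entrainer": pd.NA,
        "n_steps": len(trimmed_timing),
    }
    if session.has_music:
        esession = dataclasses.replace(session, step_events=timing_events) \
            if timing_events is not session.step_events else session
        summary = entrainment_summary(esession, config)
        row.update(
            tempo_entrainment=summary.tempo_entrainment,
            mean_rpa=np.nan if summary.mean_rpa is None else summary.mean_rpa,
            rvl=summary.rvl,
            is_entrainer=summary.is_entrainer,
            n_steps=summary.n_steps_analyzed,
        )
    return row


def build_feature_table(sessions: dict[str, dict[str, SessionRecord]],
                        cohort_info: pd.DataFrame, config: RunConfig,
                        use_detection: bool = True) -> pd.DataFrame:
    """One row per (runner, analyzed condition) with features and covariates.

    ``cohort_info`` must carry runner_id, sex, musically_trained,
    music_habit.
    """
    rows = []
    for runner_id, by_cond in sessions.items():
        for cond in ANALYZED_CONDITIONS:
            if cond in by_cond:
                rows.append(session_features(by_cond[cond], config, use_detection))
    table = pd.DataFrame(rows)
    info = cohort_info[["runner_id", "sex", "musically_trained", "music_habit"]]
    return table.merge(info, on="runner_id", how="left")


# ---------------------------------------------------------------------------
# descriptive and inferential statistics

def condition_summary(table: pd.DataFrame, feature: str) -> pd.DataFrame:
    """Per-condition, per-sex mean, standard error and count of a feature."""
    if feature not in table.columns:
        raise ValueError(f"unknown feature {feature!r}")
    groups = table.groupby(["condition", "sex"], observed=True)[feature]
    out = groups.agg(mean="mean", sd="std", n="count").reset_index()
    out["se"] = out["sd"] / np.sqrt(out["n"].clip(lower=1))
    return out[["condition", "sex", "mean", "se", "n"]]


def _complete_cases(table: pd.DataFrame, feature: str,
                    conditions: tuple[str, ...]) -> pd.DataFrame:
    sub = table[table["condition"].isin(conditions)]
    wide = sub.pivot(index="runner_id", columns="condition", values=feature)
    wide = wide.reindex(columns=list(conditions)).dropna()
    long = wide.reset_index().melt(id_vars="runner_id", var_name="condition",
                                   value_name=feature)
    info = table[["runner_id", "sex"]].drop_duplicates()
    return long.merge(info, on="runner_id")


def _pingouin_mixed(long: pd.DataFrame, feature: str) -> pd.DataFrame:
    import pingouin as pg

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pg.mixed_anova(data=long, dv=feature, within="condition",
                              between="sex", subject="runner_id")


def _mixed_ss_fallback(long: pd.DataFrame, feature: str) -> pd.DataFrame:
    """Direct mixed-design sums-of-squares decomposition.

    Used when the primary routine cannot handle degenerate data (e.g. a
    feature constant within every runner, where the sphericity estimate
    is undefined). Zero-over-zero F ratios are reported as 0.
    """
    wide = long.pivot(index="runner_id", columns="condition", values=feature)
    sex = long.drop_duplicates("runner_id").set_index("runner_id")["sex"]
    values = wide.to_numpy(float)
    groups = sex.reindex(wide.index).to_numpy()
    n, b = values.shape
    labels = np.unique(groups)
    a = labels.size
    grand = values.mean()
    ss_between_subj = b * ((values.mean(axis=1) - grand) ** 2).sum()
    ss_group = sum(b * (groups == g).sum() * (values[groups == g].mean() - grand) ** 2
                   for g in labels)
    ss_subj = ss_between_subj - ss_group
    cond_means = values.mean(axis=0)
    ss_cond = n * ((cond_means - grand) ** 2).sum()
    ss_inter = sum(
        (groups == g).sum() * (values[groups == g][:, j].mean()
                               - cond_means[j] - values[groups == g].mean() + grand) ** 2
        for g in labels for j in range(b))
    ss_total = ((values - grand) ** 2).sum()
    ss_err = max(ss_total - ss_between_subj - ss_cond - ss_inter, 0.0)

    def row(source, ss_eff, df1, ss_e, df2):
        ms_eff = ss_eff / df1
        ms_err = ss_e / df2 if df2 > 0 else 0.0
        F = 0.0 if ms_eff == 0 else (np.inf if ms_err == 0 else ms_eff / ms_err)
        p = 1.0 if F == 0 else float(sps.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
        np2 = 0.0 if ss_eff == 0 else ss_eff / (ss_eff + ss_e)
        return {"Source": source, "SS": ss_eff, "DF1": df1, "DF2": df2,
                "F": F, "p_unc": p, "np2": np2}

    return pd.DataFrame([
        row("sex", ss_group, a - 1, ss_subj, n - a),
        row("condition", ss_cond, b - 1, ss_err, (n - a) * (b - 1)),
        row("Interaction", ss_inter, (a - 1) * (b - 1), ss_err, (n - a) * (b - 1)),
    ])


def _mixed_table(long: pd.DataFrame, feature: str) -> pd.DataFrame:
    try:
        return _pingouin_mixed(long, feature)
    except Exception:  # degenerate input; use the direct decomposition
        return _mixed_ss_fallback(long, feature)


def _report_from_row(effect: str, row, columns) -> EffectReport:
    pcol = "p_unc" if "p_unc" in columns else "p-unc"
    F = float(row["F"])
    p = float(row[pcol])
    eta2 = float(row["np2"])
    if not np.isfinite(F):
        # zero effect SS over zero error SS (e.g. feature constant within
        # every runner): report a null effect rather than NaN
        F, p, eta2 = 0.0, 1.0, 0.0
    return EffectReport(
        effect=effect, statistic_name="F", statistic=F,
        df1=float(row["DF1"]), df2=float(row["DF2"]),
        p=float(min(max(p, 0.0), 1.0)),
        eta2=float(np.clip(eta2, 0.0, 1.0)) if np.isfinite(eta2) else 0.0,
    )


def mixed_design_anova(table: pd.DataFrame, feature: str,
                       include_contrasts: bool = True) -> list[EffectReport]:
    """Mixed-design ANOVA of one feature: condition, sex, condition x sex,
    plus pairwise within-subject condition contrasts.

    Complete cases only: runners observed (non-missing) in every analyzed
    condition of the feature. Music-dependent features use the two music
    conditions; mean rPA thereby includes only runners at or above the
    RVL cutoff in both music conditions (the values are missing
    otherwise). Uncorrected (sphericity-assuming) F tests are reported.
    """
    if feature not in table.columns:
        raise ValueError(f"unknown feature {feature!r}")
    conditions = MUSIC_CONDITIONS if feature in MUSIC_ONLY_FEATURES else ANALYZED_CONDITIONS
    long = _complete_cases(table, feature, conditions)
    counts = long.drop_duplicates("runner_id")["sex"].value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise InsufficientDataError(
            f"{feature}: need >= 2 complete-case runners per sex, got {counts.to_dict()}"
        )
    aov = _mixed_table(long, feature)
    name_map = {"sex": "sex", "condition": "condition", "interaction": "condition x sex"}
    reports = []
    for _, r in aov.iterrows():
        reports.append(_report_from_row(
            name_map.get(str(r["Source"]).lower(), str(r["Source"])), r, aov.columns))
    if include_contrasts and len(conditions) > 2:
        # pairwise within-subject contrasts (1-df condition effects)
        for a, b in itertools.combinations(conditions, 2):
            pair = long[long["condition"].isin((a, b))]
            sub_aov = _mixed_table(pair, feature)
            row = sub_aov[sub_aov["Source"].str.lower() == "condition"].iloc[0]
            reports.append(_report_from_row(f"condition: {a} vs {b}", row, sub_aov.columns))
    return reports


def friedman_with_posthoc(ratings: pd.DataFrame) -> tuple[EffectReport, list[EffectReport]]:
    """Friedman's ANOVA over conditions plus Bonferroni-corrected Wilcoxon
    signed-rank follow-ups.

    ``ratings`` is wide: one row per runner, one column per condition.
    Post-hoc p values are multiplied by the number of condition pairs and
    capped at 1. The Wilcoxon effect size is estimated as ``z^2 / (2n)``.
    """
    wide = ratings.dropna()
    if wide.shape[1] < 2 or wide.shape[0] < 2:
        raise InsufficientDataError("need >= 2 conditions and >= 2 complete-case runners")
    k = wide.shape[1]
    n = wide.shape[0]
    if (wide.nunique(axis=1) == 1).all():
        logger.warning("all ratings identical within every runner; Friedman statistic is 0")
        main = EffectReport("ratings", "chi2", 0.0, float(k - 1), None, 1.0)
    else:
        stat, p = sps.friedmanchisquare(*[wide[c].to_numpy() for c in wide.columns])
        main = EffectReport("ratings", "chi2", float(stat), float(k - 1), None, float(p))
    pairs = list(itertools.combinations(wide.columns, 2))
    posthoc = []
    for a, b in pairs:
        d = wide[a].to_numpy(dtype=float) - wide[b].to_numpy(dtype=float)
        if np.all(d == 0):
            z, p = 0.0, 1.0
        else:
            res = sps.wilcoxon(d, alternative="two-sided", method="approx",
                               correction=False)
            z = float(getattr(res, "zstatistic", np.nan))
            p = float(res.pvalue)
        posthoc.append(EffectReport(
            effect=f"{a} vs {b}",
            statistic_name="z",
            statistic=z,
            df1=float(n),
            df2=None,
            p=float(min(p * len(pairs), 1.0)),
            eta2=float(min(z * z / (2.0 * n), 1.0)),
        ))
    return main, posthoc


def subgroup_tests(table: pd.DataFrame,
                   features: tuple[str, ...] = ("tempo_entrainment", "rvl"),
                   ) -> dict[str, list[EffectReport]]:
    """Musical-training t-test and music-habit one-way ANOVA per feature.

    Each runner contributes one value per feature: the mean over the
    music conditions. The t-test pools variances (two-sided); eta squared
    is ``t^2 / (t^2 + df)`` and ``SS_between / SS_total`` respectively.
    """
    for col in ("musically_trained", "music_habit"):
        if col not in table.columns:
            raise ValueError(f"feature table lacks {col!r}")
    music = table[table["condition"].isin(MUSIC_CONDITIONS)]
    per_runner = music.groupby("runner_id").agg(
        **{f: (f, "mean") for f in features},
        musically_trained=("musically_trained", "first"),
        music_habit=("music_habit", "first"),
    ).reset_index()

    out: dict[str, list[EffectReport]] = {}
    for feature in features:
        data = per_runner.dropna(subset=[feature])
        reports = []
        trained = data[data["musically_trained"].astype(bool)][feature].to_numpy(float)
        untrained = data[~data["musically_trained"].astype(bool)][feature].to_numpy(float)
        if min(trained.size, untrained.size) < 2:
            raise InsufficientDataError(f"{feature}: musical-training subgroup with n < 2")
        t, df, p = pooled_t_test(untrained, trained)
        reports.append(EffectReport(
            effect=f"{feature}: musical training (untrained - trained)",
            statistic_name="t", statistic=t, df1=df, df2=None,
            p=p, eta2=float(t * t / (t * t + df)),
        ))
        groups = [g[feature].to_numpy(float) for _, g in data.groupby("music_habit")]
        if len(groups) < 2 or min(g.size for g in groups) < 2:
            raise InsufficientDataError(f"{feature}: music-habit subgroup with n < 2")
        F, df1, df2, p, eta2 = one_way_anova(groups)
        reports.append(EffectReport(
            effect=f"{feature}: music habit",
            statistic_name="F", statistic=F, df1=df1, df2=df2, p=p, eta2=eta2,
        ))
        out[feature] = reports
    return out


def pooled_t_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Two-sided pooled-variance two-sample t-test: (t, df, p).

    Identical zero-variance groups give t = 0, p = 1 (rather than NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    diff = x.mean() - y.mean()
    if sp2 == 0:
        t = 0.0 if diff == 0 else float(np.sign(diff) * np.inf)
    else:
        t = float(diff / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2)))
    p = float(2.0 * sps.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    return t, float(df), p


def one_way_anova(groups: list[np.ndarray]) -> tuple[float, float, float, float, float]:
    """One-way fixed-effects ANOVA: (F, df1, df2, p, eta2).

    Zero between- and within-group variance gives F = 0, p = 1.
    """
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1 = float(len(groups) - 1)
    df2 = float(all_vals.size - len(groups))
    if ss_within == 0:
        F = 0.0 if ss_between == 0 else float(np.inf)
    else:
        F = float((ss_between / df1) / (ss_within / df2))
    p = float(sps.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    eta2 = 0.0 if ss_between + ss_within == 0 else float(ss_between / (ss_between + ss_within))
    return F, df1, df2, p, eta2
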
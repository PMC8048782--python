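"""Condition-level statistics: mixed ANOVA, Friedman/Wilcoxon, subgroup tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from runsync import (
    condition_summary,
    friedman_with_posthoc,
    mixed_design_anova,
    subgroup_tests,
)
from runsync.stats import InsufficientDataError, one_way_anova, pooled_t_test

CONDITIONS = ("no_music", "uninstructed", "instructed")


def long_table(values: np.ndarray, sexes: list[str]) -> pd.DataFrame:
    """values[i, j]: runner i, condition j -> minimal feature table."""
    rows = []
    for i, sex in enumerate(sexes):
        for j, cond in enumerate(CONDITIONS):
            rows.append({"runner_id": f"r{i:03d}", "condition": cond,
                         "sex": sex, "cadence": values[i, j]})
    return pd.DataFrame(rows)


def brute_force_mixed_anova(values: np.ndarray, groups: np.ndarray) -> dict:
    """Direct sums-of-squares decomposition of a balanced mixed design.

    values[i, j]: subject i, within-level j; groups[i]: between-group label.
    Returns F statistics, partial eta squared, and the SS components.
    """
    n, b = values.shape
    labels = np.unique(groups)
    a = labels.size
    grand = values.mean()
    subj_means = values.mean(axis=1)
    cond_means = values.mean(axis=0)
    ss_total = ((values - grand) ** 2).sum()
    ss_between_subj = b * ((subj_means - grand) ** 2).sum()
    ss_group = sum(b * (groups == g).sum() * (values[groups == g].mean() - grand) ** 2
                   for g in labels)
    ss_subj_within = ss_between_subj - ss_group
    ss_cond = n * ((cond_means - grand) ** 2).sum()
    ss_inter = 0.0
    for g in labels:
        cell = values[groups == g]
        g_mean = cell.mean()
        for j in range(b):
            ss_inter += cell.shape[0] * (cell[:, j].mean() - cond_means[j] - g_mean + grand) ** 2
    ss_err_within = ss_total - ss_between_subj - ss_cond - ss_inter
    df_group, df_subj = a - 1, n - a
    df_cond, df_inter, df_err = b - 1, (a - 1) * (b - 1), (n - a) * (b - 1)
    return {
        "ss": dict(total=ss_total, group=ss_group, subj=ss_subj_within,
                   cond=ss_cond, inter=ss_inter, err=ss_err_within),
        "F_group": (ss_group / df_group) / (ss_subj_within / df_subj),
        "F_cond": (ss_cond / df_cond) / (ss_err_within / df_err),
        "F_inter": (ss_inter / df_inter) / (ss_err_within / df_err),
        "np2_group": ss_group / (ss_group + ss_subj_within),
        "np2_cond": ss_cond / (ss_cond + ss_err_within),
        "np2_inter": ss_inter / (ss_inter + ss_err_within),
    }


class TestConditionSummary:
    def test_constant_feature(self):
        table = long_table(np.full((4, 3), 5.0), ["male", "female"] * 2)
        out = condition_summary(table, "cadence")
        assert np.allclose(out["mean"], 5.0)
        assert np.allclose(out["se"], 0.0)

    def test_two_runner_cell(self):
        values = np.full((4, 3), 2.0)
        values[0, 0], values[2, 0] = 1.0, 3.0  # the two males, no_music
        table = long_table(values, ["male", "female", "male", "female"])
        out = condition_summary(table, "cadence")
        cell = out[(out["condition"] == "no_music") & (out["sex"] == "male")].iloc[0]
        assert cell["mean"] == 2.0
        assert cell["se"] == pytest.approx(1.0)  # sd sqrt(2) over sqrt(2)
        assert cell["n"] == 2

    def test_unknown_feature_rejected(self):
        table = long_table(np.zeros((2, 3)), ["male", "female"])
        with pytest.raises(ValueError):
            condition_summary(table, "vo2max")


class TestMixedDesignAnova:
    def test_constant_within_runner_gives_zero_condition_F(self):
        rng = np.random.default_rng(0)
        base = rng.normal(170.0, 5.0, size=6)
        values = np.repeat(base[:, None], 3, axis=1)
        table = long_table(values, ["male", "female"] * 3)
        reports = {r.effect: r for r in mixed_design_anova(table, "cadence")}
        assert reports["condition"].statistic == 0.0
        assert reports["condition"].p == 1.0

    def test_matches_brute_force_decomposition(self):
        """F and partial eta squared agree with direct SS arithmetic to 1e-8."""
        rng = np.random.default_rng(12)
        sexes = ["male"] * 3 + ["female"] * 3
        values = (rng.normal(170, 4, size=(6, 1))
                  + np.array([0.0, 2.0, 1.5])
                  + rng.normal(0, 1, size=(6, 3)))
        values[3:] += 5.0  # sex effect
        table = long_table(values, sexes)
        oracle = brute_force_mixed_anova(values, np.array(sexes))
        reports = {r.effect: r for r in mixed_design_anova(table, "cadence")}
        assert reports["condition"].statistic == pytest.approx(oracle["F_cond"], abs=1e-8)
        assert reports["sex"].statistic == pytest.approx(oracle["F_group"], abs=1e-8)
        assert reports["condition x sex"].statistic == pytest.approx(
            oracle["F_inter"], abs=1e-8)
        assert reports["condition"].eta2 == pytest.approx(oracle["np2_cond"], abs=1e-8)
        assert reports["sex"].eta2 == pytest.approx(oracle["np2_group"], abs=1e-8)
        assert reports["condition"].df1 == 2 and reports["condition"].df2 == 8
        # contrasts present for all three condition pairs
        assert sum(r.effect.startswith("condition:") for r in
                   mixed_design_anova(table, "cadence")) == 3

    def test_ss_decomposition_is_additive(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=(8, 3))
        oracle = brute_force_mixed_anova(values, np.array(["m"] * 4 + ["f"] * 4))
        ss = oracle["ss"]
        assert ss["group"] + ss["subj"] + ss["cond"] + ss["inter"] + ss["err"] == \
            pytest.approx(ss["total"], abs=1e-8)
        assert all(v >= -1e-12 for v in ss.values())

    def test_insufficient_sexes_rejected(self):
        table = long_table(np.random.default_rng(1).normal(size=(3, 3)), ["male"] * 3)
        with pytest.raises(InsufficientDataError):
            mixed_design_anova(table, "cadence")

    def test_planted_effect_power(self):
        """A condition effect sized for 90 % nominal power is detected in
        >= 80 % of 200 simulated cohorts of 33 runners."""
        n, alpha = 33, 0.05
        df1, df2 = 2, (n - 2) * 2
        crit = sps.f.ppf(1 - alpha, df1, df2)

        def power(d):
            lam = n * (2.0 / 3.0) * d * d
            return sps.ncf.sf(crit, df1, df2, lam)

        lo, hi = 0.01, 3.0
        while hi - lo > 1e-6:
            mid = (lo + hi) / 2
            lo, hi = (mid, hi) if power(mid) < 0.90 else (lo, mid)
        d = hi
        assert 0.85 < power(d) < 0.95
        rng = np.random.default_rng(99)
        sexes = ["male"] * 16 + ["female"] * 17
        hits = 0
        for _ in range(200):
            values = (rng.normal(0, 1, size=(n, 1)) + np.array([0.0, d, d])
                      + rng.normal(0, 1, size=(n, 3)))
            table = long_table(values, sexes)
            rep = {r.effect: r for r in
                   mixed_design_anova(table, "cadence", include_contrasts=False)}
            hits += rep["condition"].p < alpha
        assert hits >= 160

    def test_null_type_one_error_calibrated(self):
        """Without a condition effect the 5 % test rejects in 5 % +/- 2 %
        of 1000 simulated cohorts."""
        rng = np.random.default_rng(1234)
        sexes = ["male"] * 16 + ["female"] * 17
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            values = rng.normal(0, 1, size=(33, 1)) + rng.normal(0, 1, size=(33, 3))
            table = long_table(values, sexes)
            rep = {r.effect: r for r in
                   mixed_design_anova(table, "cadence", include_contrasts=False)}
            rejections += rep["condition"].p < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_rpa_uses_complete_cases_only(self):
        """Runners missing mean rPA in either music condition drop out."""
        rng = np.random.default_rng(4)
        rows = []
        for i in range(8):
            sex = "male" if i % 2 else "female"
            for cond in ("uninstructed", "instructed"):
                val = rng.normal(-40, 10)
                if i in (0, 1) and cond == "uninstructed":
                    val = np.nan  # gated by low RVL
                rows.append({"runner_id": f"r{i}", "condition": cond,
                             "sex": sex, "mean_rpa": val})
        reports = {r.effect: r for r in
                   mixed_design_anova(pd.DataFrame(rows), "mean_rpa")}
        # 6 complete-case runners -> condition df2 = 6 - 2 = 4
        assert reports["condition"].df2 == 4


class TestFriedman:
    def test_identical_ratings_give_zero(self, caplog):
        wide = pd.DataFrame({c: [3.0, 4.0, 5.0, 2.0] for c in CONDITIONS})
        with caplog.at_level("WARNING"):
            main, posthoc = friedman_with_posthoc(wide)
        assert main.statistic == 0.0
        assert all(p.p == 1.0 for p in posthoc)

    def test_matches_brute_force_ranks(self):
        wide = pd.DataFrame({
            "no_music": [4.0, 5.0, 3.0, 4.5],
            "uninstructed": [5.0, 6.0, 4.0, 5.5],
            "instructed": [4.5, 5.5, 5.0, 5.0],
        })
        main, _ = friedman_with_posthoc(wide)
        ranks = np.array([sps.rankdata(row) for row in wide.to_numpy()])
        n, k = ranks.shape
        chi2 = 12.0 * n / (k * (k + 1)) * ((ranks.mean(axis=0) - (k + 1) / 2.0) ** 2).sum()
        assert main.statistic == pytest.approx(chi2, abs=1e-10)

    def test_bonferroni_caps_at_one(self):
        rng = np.random.default_rng(6)
        wide = pd.DataFrame(rng.normal(5, 1, size=(10, 3)), columns=CONDITIONS)
        _, posthoc = friedman_with_posthoc(wide)
        assert len(posthoc) == 3
        assert all(0.0 <= p.p <= 1.0 for p in posthoc)

    def test_planted_shift_detected(self):
        """A one-condition shift in 33 runners is flagged in >= 90 % of 200
        replicates at alpha = 0.05."""
        rng = np.random.default_rng(77)
        hits = 0
        for _ in range(200):
            base = rng.normal(5.0, 1.0, size=(33, 1)) + rng.normal(0, 0.7, size=(33, 3))
            base[:, 0] -= 0.8  # lower enjoyment without music
            main, _ = friedman_with_posthoc(pd.DataFrame(base, columns=CONDITIONS))
            hits += main.p < 0.05
        assert hits >= 180

    def test_too_small_rejected(self):
        with pytest.raises(InsufficientDataError):
            friedman_with_posthoc(pd.DataFrame({"a": [1.0]}))


class TestSubgroups:
    @staticmethod
    def feature_table(rvl_trained, rvl_untrained, habit=None):
        rows = []
        vals = list(rvl_trained) + list(rvl_untrained)
        trained = [True] * len(rvl_trained) + [False] * len(rvl_untrained)
        habit = habit or ["with", "without", "both"] * (len(vals) // 3 + 1)
        for i, (v, tr) in enumerate(zip(vals, trained)):
            for cond in ("uninstructed", "instructed"):
                rows.append({"runner_id": f"r{i}", "condition": cond,
                             "tempo_entrainment": v * 100.0, "rvl": v,
                             "musically_trained": tr, "music_habit": habit[i]})
        return pd.DataFrame(rows)

    def test_identical_groups_give_zero_statistics(self):
        table = self.feature_table([0.5] * 4, [0.5] * 4)
        out = subgroup_tests(table)
        for feature in ("tempo_entrainment", "rvl"):
            t_rep, f_rep = out[feature]
            assert t_rep.statistic == 0.0 and t_rep.p == 1.0
            assert f_rep.statistic == 0.0 and f_rep.p == 1.0

    def test_pooled_t_matches_hand_computation(self):
        t, df, p = pooled_t_test(np.array([0.2, 0.4, 0.6]), np.array([0.5, 0.7, 0.9]))
        # means 0.4 vs 0.7, pooled var 0.04 -> t = -0.3 / (0.2 * sqrt(2/3))
        assert t == pytest.approx(-0.3 / (0.2 * np.sqrt(2.0 / 3.0)), abs=1e-10)
        assert df == 4
        assert p == pytest.approx(2 * sps.t.sf(abs(t), 4), abs=1e-12)

    def test_one_way_anova_matches_scipy(self):
        rng = np.random.default_rng(8)
        groups = [rng.normal(size=5), rng.normal(0.5, 1, size=6), rng.normal(1, 1, size=4)]
        F, df1, df2, p, eta2 = one_way_anova(groups)
        F_sp, p_sp = sps.f_oneway(*groups)
        assert F == pytest.approx(F_sp, abs=1e-10)
        assert p == pytest.approx(p_sp, abs=1e-12)

    def test_planted_training_gap_direction(self):
        """With a genuine trained > untrained RVL gap, the reported contrast
        points the right way in >= 95 % of replicates."""
        rng = np.random.default_rng(55)
        hits = 0
        for _ in range(100):
            trained = rng.normal(0.7, 0.15, size=12)
            untrained = rng.normal(0.5, 0.15, size=21)
            table = self.feature_table(np.clip(trained, 0, 1), np.clip(untrained, 0, 1))
            t_rep = subgroup_tests(table)["rvl"][0]
            hits += t_rep.statistic < 0  # untrained minus trained
        assert hits >= 95

    def test_small_subgroup_rejected(self):
        table = self.feature_table([0.5], [0.4] * 5)
        with pytest.raises(InsufficientDataError):
            subgroup_tests(table)
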
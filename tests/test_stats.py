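"""Repeated-measures ANOVA, pairwise follow-ups, correlations, responder split."""

import itertools

import numpy as np
import pandas as pd
import pytest

from spatialhear import stats
from spatialhear.stats import (bonferroni_pairwise, classify_responders,
                               correlate, correlation_table, rm_anova)


def synthetic_cells(n_subjects=8, seed=0, subject_sd=2.0, noise_sd=1.0,
                    effects=None):
    """Cell table with known additive structure: grand mean + subject + effects + noise."""
    rng = np.random.default_rng(seed)
    conditions = ["NH", "NH-LPF", "OTE", "OTE-LPF", "ITE", "ITE-LPF"]
    effects = effects or {}
    rows = []
    for i in range(n_subjects):
        subj_eff = rng.normal(0, subject_sd)
        for c in conditions:
            for q in (5, 10):
                for h in ("front", "back"):
                    y = 50.0 + subj_eff
                    y += effects.get("condition", {}).get(c, 0.0)
                    y += effects.get("snr_db", {}).get(q, 0.0)
                    y += effects.get("hemifield", {}).get(h, 0.0)
                    y += rng.normal(0, noise_sd)
                    rows.append({"subject": f"S{i:02d}", "condition": c,
                                 "snr_db": q, "hemifield": h, "dv": y})
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_seven_effects_with_correct_dfs(self, cells):
        table = rm_anova(cells, "rau").set_index("effect")
        assert len(table) == 7
        n = cells["subject"].nunique()
        assert table.loc["condition", ["df_num", "df_den"]].tolist() == [5, 5 * (n - 1)]
        assert table.loc["snr_db", ["df_num", "df_den"]].tolist() == [1, n - 1]
        assert table.loc["condition x snr_db x hemifield",
                         ["df_num", "df_den"]].tolist() == [5, 5 * (n - 1)]

    def test_matches_statsmodels_anovarm(self, cells):
        """Dual-route check: full three-factor table against statsmodels."""
        anova_rm = pytest.importorskip("statsmodels.stats.anova").AnovaRM
        ref = anova_rm(cells, depvar="rau", subject="subject",
                       within=["condition", "snr_db", "hemifield"]).fit().anova_table
        mine = rm_anova(cells, "rau").set_index("effect")
        for sm_name in ref.index:
            my_name = " x ".join(sm_name.split(":"))
            assert mine.loc[my_name, "F"] == pytest.approx(
                ref.loc[sm_name, "F Value"], rel=1e-8)
            assert mine.loc[my_name, "df_num"] == ref.loc[sm_name, "Num DF"]
            assert mine.loc[my_name, "df_den"] == ref.loc[sm_name, "Den DF"]

    def test_hand_computed_two_by_two(self):
        """4 subjects, 2x2 within factors (third factor absorbed): SS computed
        by the textbook marginal-mean formulas inside the test."""
        rng = np.random.default_rng(42)
        data = rng.normal(10, 3, size=(4, 2, 2, 2))
        rows = []
        for s, c, q, h in itertools.product(range(4), range(2), range(2), range(2)):
            rows.append({"subject": f"S{s}", "condition": ["A", "B"][c],
                         "snr_db": [5, 10][q], "hemifield": ["front", "back"][h],
                         "dv": data[s, c, q, h]})
        cells = pd.DataFrame(rows)
        table = rm_anova(cells, "dv").set_index("effect")

        # textbook oracle for the condition main effect
        n, a = 4, 2
        cell_per = 4  # observations per subject x condition
        m_sc = data.mean(axis=(2, 3))          # subject x condition means
        m_s = data.mean(axis=(1, 2, 3))
        m_c = data.mean(axis=(0, 2, 3))
        grand = data.mean()
        ss_c = n * cell_per * np.sum((m_c - grand) ** 2)
        ss_cs = cell_per * np.sum((m_sc - m_s[:, None] - m_c[None, :] + grand) ** 2)
        f_oracle = (ss_c / (a - 1)) / (ss_cs / ((a - 1) * (n - 1)))
        assert table.loc["condition", "F"] == pytest.approx(f_oracle, rel=1e-10)
        assert table.loc["condition", "partial_eta_sq"] == pytest.approx(
            ss_c / (ss_c + ss_cs), rel=1e-10)

    def test_decomposition_identity(self, cells):
        std = cells.copy()
        std["rau"] = (std["rau"] - std["rau"].mean()) / std["rau"].std()
        assert stats.decomposition_residual(std, "rau") < 1e-8

    def test_partial_eta_sq_matches_f_df_identity(self, cells):
        t = rm_anova(cells, "rau")
        alt = t["F"] * t["df_num"] / (t["F"] * t["df_num"] + t["df_den"])
        assert np.allclose(t["partial_eta_sq"], alt, atol=1e-10)

    def test_gg_epsilon_matches_pingouin(self, cells):
        pg = pytest.importorskip("pingouin")
        wide = cells.groupby(["subject", "condition"])["rau"].mean().unstack()
        eps = pg.epsilon(wide, correction="gg")
        mine = rm_anova(cells, "rau").set_index("effect")
        assert mine.loc["condition", "gg_epsilon"] == pytest.approx(eps, abs=1e-8)
        # single-df effects are trivially spherical
        assert mine.loc["snr_db", "gg_epsilon"] == 1.0

    def test_constant_dv_reported_degenerate(self):
        cells = synthetic_cells(noise_sd=0.0, subject_sd=0.0)
        table = rm_anova(cells, "dv")
        assert ((table["F"] == 0) | ~np.isfinite(table["F"])).all()

    def test_null_f_near_null_expectation(self):
        """Pure subject + noise data: mean F over replicates near df_den/(df_den-2)."""
        fs = []
        for seed in range(120):
            cells = synthetic_cells(n_subjects=6, seed=seed)
            t = rm_anova(cells, "dv").set_index("effect")
            fs.append(t.loc["snr_db", "F"])
        df_den = 5
        expected = df_den / (df_den - 2)  # mean of F(1, 5)
        assert np.mean(fs) == pytest.approx(expected, rel=0.35)

    def test_row_order_and_subject_relabeling_invariance(self, cells):
        base = rm_anova(cells, "rau")
        shuffled = cells.sample(frac=1.0, random_state=0)
        relabeled = shuffled.copy()
        relabeled["subject"] = relabeled["subject"].map(
            {s: f"listener-{i}" for i, s in enumerate(sorted(cells["subject"].unique()))})
        pd.testing.assert_frame_equal(
            base.drop(columns="effect"),
            rm_anova(relabeled, "rau").drop(columns="effect"), atol=1e-10)

    def test_missing_cell_rejected_with_subject_named(self, cells):
        broken = cells.drop(cells[(cells["subject"] == "S03")
                                  & (cells["condition"] == "OTE")
                                  & (cells["snr_db"] == 5)
                                  & (cells["hemifield"] == "back")].index)
        with pytest.raises(ValueError, match="S03"):
            rm_anova(broken, "rau")

    def test_fewer_than_three_subjects_rejected(self, cells):
        two = cells[cells["subject"].isin(["S01", "S02"])]
        with pytest.raises(ValueError, match="3 subjects"):
            rm_anova(two, "rau")


class TestPairwise:
    def test_six_level_factor_gives_15_comparisons(self, cells):
        out = bonferroni_pairwise(cells, "rau", "condition")
        assert len(out) == 15
        assert (out["p_bonferroni"] <= 1.0).all()
        assert (out["p_bonferroni"] >= out["p_raw"] - 1e-12).all()

    def test_identical_levels_give_zero_difference_p_one(self):
        cells = synthetic_cells(noise_sd=0.0)
        # remove any per-draw noise differences between two levels
        wide = cells.pivot_table(index=["subject", "snr_db", "hemifield"],
                                 columns="condition", values="dv").reset_index()
        wide["NH-LPF"] = wide["NH"]
        cells2 = wide.melt(id_vars=["subject", "snr_db", "hemifield"],
                           var_name="condition", value_name="dv")
        out = bonferroni_pairwise(cells2, "dv", "condition").set_index(
            ["level_a", "level_b"])
        key = ("NH", "NH-LPF") if ("NH", "NH-LPF") in out.index else ("NH-LPF", "NH")
        assert out.loc[key, "mean_difference"] == pytest.approx(0.0)
        assert out.loc[key, "p_bonferroni"] == 1.0

    def test_injected_condition_contrast_detected(self):
        cells = synthetic_cells(
            n_subjects=10, seed=5,
            effects={"condition": {"ITE-LPF": -8.0}})
        out = bonferroni_pairwise(cells, "dv", "condition").set_index(
            ["level_a", "level_b"])
        key = ("NH", "ITE-LPF")
        assert out.loc[key, "p_bonferroni"] < 0.05
        assert out.loc[key, "mean_difference"] > 0

    def test_single_level_rejected(self, cells):
        only = cells[cells["condition"] == "NH"]
        with pytest.raises(ValueError, match="2 levels"):
            bonferroni_pairwise(only, "rau", "condition")


class TestCorrelate:
    def test_perfect_and_negative_correlation(self, rng):
        x = rng.normal(size=50)
        df = pd.DataFrame({"x": x, "y": x})
        r, p = correlate(df, "x", "y")
        assert r == pytest.approx(1.0)
        df["y"] = -x + rng.normal(0, 0.2, 50)
        r, _ = correlate(df, "x", "y")
        assert r < -0.9

    def test_zero_variance_undefined(self):
        df = pd.DataFrame({"x": [1.0, 1.0, 1.0], "y": [1.0, 2.0, 3.0]})
        r, p = correlate(df, "x", "y")
        assert np.isnan(r) and np.isnan(p)

    def test_too_few_observations_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "y": [1.0, 2.0]})
        with pytest.raises(ValueError, match="3 paired"):
            correlate(df, "x", "y")

    def test_independence_gives_small_r(self):
        """Independent generator channels: |r| < 0.2 in most replicates at n=240."""
        rng = np.random.default_rng(11)
        small = 0
        for _ in range(40):
            df = pd.DataFrame({"x": rng.normal(size=240), "y": rng.normal(size=240)})
            r, _ = correlate(df, "x", "y")
            small += abs(r) < 0.2
        assert small >= 38

    def test_correlation_table_shape(self, cells, cohort):
        out = correlation_table(cells)
        assert len(out) == 3
        assert out["pearson_r"].abs().le(1).all()


class TestResponders:
    def test_cutoff_rule(self):
        resp = pd.DataFrame({"subject": ["A"] * 3 + ["B"] * 3,
                             "rt_s": [0.6, 0.6, 0.6, 2.0, 2.0, 2.0]})
        out = classify_responders(resp).set_index("subject")
        assert out.loc["A", "responder_class"] == "fast"
        assert out.loc["B", "responder_class"] == "slow"

    def test_cohort_slow_archetypes_recovered_exactly(self, cohort):
        out = classify_responders(cohort.responses).set_index("subject")
        truth = cohort.truth.groupby("subject")["responder_class"].first()
        assert (out["responder_class"] == truth.loc[out.index]).all()
        assert (out["responder_class"] == "slow").sum() == 3

    def test_empty_rts_rejected(self):
        with pytest.raises(ValueError, match="no reaction times"):
            classify_responders(pd.DataFrame({"subject": ["A"], "rt_s": [np.nan]}))
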
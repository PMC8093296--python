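"""Trial filtering, epoch aggregation, cueing effects, and the RM-ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ccdm.behavior import (
    aggregate_epochs,
    contextual_cueing,
    filter_trials,
    pairwise_posthoc,
    rm_anova,
)


def make_table(rts, correct=None, subject=1, session="unisensory"):
    n = len(rts)
    return pd.DataFrame(
        {
            "subject": subject,
            "session": session,
            "block": np.repeat(np.arange(1, n + 1), 1)[:n] % 32 + 1,
            "epoch": 1,
            "trial_type": "unisensory_visual",
            "configuration": "old",
            "correct": correct if correct is not None else np.ones(n, dtype=int),
            "rt_ms": np.asarray(rts, dtype=float),
        }
    )


class TestFilterTrials:
    def test_floor_rule(self):
        tbl = make_table([150.0] + [1000.0] * 50)
        out, rep = filter_trials(tbl, "rt_analysis")
        assert rep.n_floor == 1
        assert 150.0 not in out["rt_ms"].values

    def test_error_trials_dropped_only_for_rt_analysis(self):
        correct = np.ones(50, dtype=int)
        correct[:5] = 0
        tbl = make_table([1000.0] * 50, correct=correct)
        out_rt, rep_rt = filter_trials(tbl, "rt_analysis")
        out_ddm, rep_ddm = filter_trials(tbl, "ddm")
        assert rep_rt.n_error == 5 and (out_rt["correct"] == 1).all()
        assert rep_ddm.n_error == 0 and len(out_ddm) == 50

    def test_zero_sd_is_noop(self):
        tbl = make_table([1000.0] * 40)
        out, rep = filter_trials(tbl, "rt_analysis")
        assert rep.n_sd_rule == 0 and len(out) == 40

    def test_constructed_outlier_is_the_single_exclusion(self):
        rng = np.random.default_rng(3)
        rts = np.concatenate([rng.normal(1000, 100, 100), [10_000.0]])
        tbl = make_table(rts)
        out, rep = filter_trials(tbl, "rt_analysis")
        assert rep.n_sd_rule == 1
        assert out["rt_ms"].max() < 10_000

    def test_idempotent_with_frozen_statistics(self):
        """Every retained trial satisfies the rule under the original mean/SD."""
        rng = np.random.default_rng(4)
        tbl = make_table(np.maximum(rng.normal(900, 250, 300), 50))
        out, _ = filter_trials(tbl, "rt_analysis")
        pre = tbl.loc[tbl["rt_ms"] >= 200, "rt_ms"]
        m, s = pre.mean(), pre.std()
        assert ((out["rt_ms"] - m).abs() <= 2.5 * s).all()
        assert (out["rt_ms"] >= 200).all()

    def test_too_few_trials_names_subject(self):
        tbl = make_table([1000.0])
        with pytest.raises(ValueError, match="1"):
            filter_trials(tbl, "rt_analysis")

    def test_reports_both_trimming_scopes(self, small_cohort):
        _, table = small_cohort
        _, rep = filter_trials(table, "rt_analysis")
        assert rep.n_sd_rule >= 0 and rep.n_sd_rule_subject_overall >= 0
        assert 0 < rep.excluded_fraction < 0.2


class TestAggregateEpochs:
    def _uniform_table(self):
        rows = []
        for subject in (1, 2):
            for cfg in ("old", "new"):
                for block in range(1, 33):
                    for _ in range(4):
                        rows.append(
                            {
                                "subject": subject,
                                "session": "unisensory",
                                "block": block,
                                "epoch": (block + 3) // 4,
                                "trial_type": "unisensory_visual",
                                "configuration": cfg,
                                "correct": 1,
                                "rt_ms": 1000.0,
                            }
                        )
        return pd.DataFrame(rows)

    def test_uniform_means_and_counts(self):
        ep = aggregate_epochs(self._uniform_table())
        assert (ep["rt_ms"] == 1000.0).all()
        assert (ep["n_trials"] == 16).all()
        assert sorted(ep["epoch"].unique()) == list(range(1, 9))

    def test_missing_epochs_raise(self):
        tbl = self._uniform_table()
        with pytest.raises(ValueError, match="empty"):
            aggregate_epochs(tbl[tbl["block"] <= 4])


class TestContextualCueing:
    def test_zero_for_equal_means(self):
        tbl = TestAggregateEpochs()._uniform_table()
        ep = aggregate_epochs(tbl)
        per, summary = contextual_cueing(ep)
        assert (per["cc_ms"] == 0).all()
        assert (summary["cc_ms"] == 0).all()

    def test_antisymmetry_under_label_swap(self, small_cohort_filtered):
        ep = aggregate_epochs(small_cohort_filtered["rt"])
        per, _ = contextual_cueing(ep)
        swapped = ep.copy()
        swapped["configuration"] = swapped["configuration"].map({"old": "new", "new": "old"})
        per_sw, _ = contextual_cueing(swapped)
        merged = per.merge(per_sw, on=["subject", "trial_type", "epoch"])
        assert np.allclose(merged["cc_ms_x"], -merged["cc_ms_y"])

    def test_positive_group_effect_in_paper_like(self, small_cohort_filtered):
        ep = aggregate_epochs(small_cohort_filtered["rt"])
        _, summary = contextual_cueing(ep)
        late = summary[summary["epoch"] >= 2]
        assert late.groupby("trial_type")["cc_ms"].mean().gt(0).all()


class TestRmAnova:
    def test_two_level_factor_equals_squared_paired_t_worked_example(self):
        data = pd.DataFrame(
            {
                "subject": [1, 2, 3, 1, 2, 3],
                "cond": ["a"] * 3 + ["b"] * 3,
                "y": [1.0, 2.0, 3.0, 2.0, 4.0, 5.0],
            }
        )
        res = rm_anova(data, dv="y", within=["cond"])
        row = res.iloc[0]
        assert row["F"] == pytest.approx(25.0, abs=1e-9)
        assert (row["df1"], row["df2"]) == (1, 2)
        assert row["partial_eta_sq"] == pytest.approx(25.0 / 27.0, abs=1e-9)

    def test_zero_mean_difference_gives_zero_f(self):
        data = pd.DataFrame(
            {
                "subject": [1, 2, 1, 2],
                "cond": ["a", "a", "b", "b"],
                "y": [1.0, 2.0, 2.0, 1.0],
            }
        )
        res = rm_anova(data, dv="y", within=["cond"])
        assert res.iloc[0]["F"] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_f_equals_squared_paired_t_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        n = 10
        data = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), 2),
                "cond": ["a", "b"] * n,
                "y": rng.normal(size=2 * n),
            }
        )
        res = rm_anova(data, dv="y", within=["cond"])
        wide = data.pivot(index="subject", columns="cond", values="y")
        t, _ = stats.ttest_rel(wide["a"], wide["b"])
        assert res.iloc[0]["F"] == pytest.approx(t**2, abs=1e-9)

    def test_three_factor_design_effects_and_gg(self, small_cohort_filtered):
        ep = aggregate_epochs(small_cohort_filtered["rt"])
        res = rm_anova(ep, dv="rt_ms", within=["trial_type", "configuration", "epoch"])
        assert len(res) == 7  # 3 mains + 3 two-way + 1 three-way
        assert (res["F"] >= 0).all()
        assert res["partial_eta_sq"].between(0, 1).all()
        eps = res.set_index("effect")["gg_epsilon"]
        assert eps["configuration"] == pytest.approx(1.0)
        k = 8
        assert 1.0 / (k - 1) - 1e-9 <= eps["epoch"] <= 1.0 + 1e-9

    def test_missing_cells_raise(self):
        data = pd.DataFrame(
            {"subject": [1, 1, 2], "cond": ["a", "b", "a"], "y": [1.0, 2.0, 3.0]}
        )
        with pytest.raises(ValueError):
            rm_anova(data, dv="y", within=["cond"])

    def test_p_values_uniform_under_null(self):
        """KS calibration: 200 pure-noise within-subject tables."""
        rng = np.random.default_rng(11)
        pvals = []
        for _ in range(200):
            data = pd.DataFrame(
                {
                    "subject": np.repeat(np.arange(8), 6),
                    "f1": ["x", "x", "x", "y", "y", "y"] * 8,
                    "f2": ["p", "q", "r"] * 16,
                    "y": rng.normal(size=48),
                }
            )
            res = rm_anova(data, dv="y", within=["f1", "f2"])
            pvals.append(res.set_index("effect").loc["f1:f2", "p"])
        _, p = stats.kstest(pvals, "uniform")
        assert p > 0.01


def test_pairwise_posthoc_bonferroni():
    rng = np.random.default_rng(5)
    data = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(10), 3),
            "cond": ["a", "b", "c"] * 10,
            "y": rng.normal(size=30),
        }
    )
    res = pairwise_posthoc(data, dv="y", factor="cond")
    assert len(res) == 3
    assert (res["p_bonferroni"] >= res["p"] - 1e-12).all()
    assert (res["p_bonferroni"] <= 1.0).all()
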
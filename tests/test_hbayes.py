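"""Model space, sampler contracts, DIC bookkeeping, and diagnostics."""

import numpy as np
import pandas as pd
import pytest

from ccdm import behavior, hbayes
from ccdm.ddm_core import DDMParameters, fpt_density
from ccdm.hbayes import (
    BY_CONDITION,
    EPOCH_COVARIATE,
    FIXED,
    ModelSpec,
    PosteriorSamples,
    build_model_space,
    compute_dic,
    fit_hierarchical,
    posterior_probability,
    rhat,
)
from ccdm.synthetic_data import default_ground_truth, simulate_cohort

SPECS = {s.model_id: s for s in build_model_space()}
QUICK_MCMC = {"n_draws": 400, "n_burn_in": 150, "n_chains": 2, "seed": 3}


@pytest.fixture(scope="module")
def quick_fit(small_cohort_filtered):
    return fit_hierarchical(SPECS[9], small_cohort_filtered["ddm"], mcmc=QUICK_MCMC)


class TestModelSpace:
    def test_exactly_fifteen_models_in_four_categories(self):
        space = build_model_space()
        assert len(space) == 15
        assert sorted(s.model_id for s in space) == list(range(1, 16))
        n_cov = sum(
            1 for s in space if EPOCH_COVARIATE in s.dependence.values()
        )
        n_fixed_all = sum(1 for s in space if set(s.dependence.values()) == {FIXED})
        n_full = sum(1 for s in space if set(s.dependence.values()) == {BY_CONDITION})
        assert (n_fixed_all, n_full, n_cov) == (1, 1, 7)
        assert 15 - n_fixed_all - n_full - n_cov == 6  # partial models

    def test_baseline_and_model_nine_structure(self):
        assert SPECS[1].dependence == {"v": FIXED, "a": FIXED, "t": FIXED}
        assert SPECS[9].dependence == {
            "v": BY_CONDITION,
            "a": EPOCH_COVARIATE,
            "t": BY_CONDITION,
        }

    def test_invalid_dependence_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(99, {"v": "quadratic", "a": FIXED, "t": FIXED})


class TestRhat:
    def test_near_one_for_jittered_copies(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=800)
        df = pd.DataFrame(
            {
                "theta": np.concatenate([base, base + rng.normal(0, 1e-4, 800)]),
                "chain": [0] * 800 + [1] * 800,
            }
        )
        assert rhat(df)["theta"] < 1.01

    def test_large_for_separated_chains(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "theta": np.concatenate(
                    [rng.normal(0, 1, 500), rng.normal(10, 1, 500)]
                ),
                "chain": [0] * 500 + [1] * 500,
            }
        )
        assert rhat(df)["theta"] > 1.5


def _dummy_samples(draws: pd.DataFrame) -> PosteriorSamples:
    return PosteriorSamples(
        spec=SPECS[8],
        group_draws=draws,
        deviance=np.zeros(len(draws)),
        subject_mean={},
        subject_snapshots=[],
        n_draws=len(draws),
        n_burn_in=0,
        n_chains=1,
        seed=0,
        rhat_values=pd.Series(dtype=float),
        converged=True,
        warnings=[],
        n_trials=0,
        n_timeout_excluded=0,
        data_hash="",
        subject_labels=np.array([]),
    )


class TestPosteriorProbability:
    def test_symmetric_posterior_near_half(self):
        rng = np.random.default_rng(2)
        s = _dummy_samples(pd.DataFrame({"x": rng.normal(0, 1, 20000), "chain": 0}))
        res = posterior_probability(s, {"x": 1.0})
        assert res.p_percent == pytest.approx(50.0, abs=2.0)

    def test_complement_identity_exact(self):
        rng = np.random.default_rng(3)
        s = _dummy_samples(pd.DataFrame({"x": rng.normal(0.3, 1, 5000), "chain": 0}))
        p = posterior_probability(s, {"x": 1.0})
        q = posterior_probability(s, lambda d: d["x"].to_numpy() <= 0)
        assert p.p_percent + q.p_percent == pytest.approx(100.0, abs=1e-12)

    def test_unknown_parameter_raises(self):
        s = _dummy_samples(pd.DataFrame({"x": [1.0], "chain": 0}))
        with pytest.raises(KeyError):
            posterior_probability(s, {"nope": 1.0})


def test_hierarchical_likelihood_matches_kernel_density():
    """The sampler's per-trial log density is the shared FPT kernel."""
    from ccdm.ddm_core import _loglik_array

    rng = np.random.default_rng(4)
    rt = rng.uniform(0.4, 2.0, 50)
    upper = rng.random(50) > 0.3
    v, a, t = 1.3, 1.7, 0.3
    ll = _loglik_array(rt, upper, np.full(50, v), np.full(50, a), np.full(50, t), 0.5)
    p = DDMParameters(v=v, a=a, t=t)
    for i in range(50):
        boundary = "upper" if upper[i] else "lower"
        assert ll[i] == pytest.approx(
            np.log(fpt_density(rt[i] - t, p, boundary)), abs=1e-10
        )


class TestFitHierarchical:
    def test_deterministic_under_seed(self, small_cohort_filtered):
        a = fit_hierarchical(
            SPECS[1],
            small_cohort_filtered["ddm"],
            mcmc={"n_draws": 120, "n_burn_in": 40, "n_chains": 1, "seed": 9},
        )
        b = fit_hierarchical(
            SPECS[1],
            small_cohort_filtered["ddm"],
            mcmc={"n_draws": 120, "n_burn_in": 40, "n_chains": 1, "seed": 9},
        )
        assert a.group_draws.equals(b.group_draws)
        assert np.array_equal(a.deviance, b.deviance)

    def test_flagging_is_consistent_with_rhat(self, quick_fit):
        flagged = bool((quick_fit.rhat_values > hbayes.RHAT_FLAG).any())
        assert quick_fit.converged == (not flagged)
        assert bool(quick_fit.warnings) == flagged

    def test_group_columns_cover_model_structure(self, quick_fit):
        cols = set(quick_fit.group_draws.columns)
        assert sum(c.startswith("v_mu[") for c in cols) == 6
        assert sum(c.startswith("t_mu[") for c in cols) == 6
        assert "a_beta0_mu" in cols
        assert sum(c.startswith("a_beta1_mu[") for c in cols) == 6

    def test_boundary_positive_over_epochs_in_posterior_means(self, quick_fit):
        base = quick_fit.subject_mean["a"]["base"]
        slope = quick_fit.subject_mean["a"]["slope"]
        for epoch in (1.0, 8.0):
            assert (base[:, [0]] + slope * epoch > 0).all()

    def test_by_condition_model_rejects_missing_cells(self, small_cohort):
        """A 6-cell model cannot fit data covering only the unisensory cells."""
        _, table = small_cohort
        uni_only = table[table["session"] == "unisensory"]
        with pytest.raises(ValueError, match="no trials in cell"):
            fit_hierarchical(SPECS[8], uni_only, mcmc=QUICK_MCMC)


class TestDic:
    def test_identity_holds_exactly(self, quick_fit, small_cohort_filtered):
        res = compute_dic(quick_fit, small_cohort_filtered["ddm"])
        assert res.dic - res.d_bar - res.p_d == 0.0
        assert res.p_d == pytest.approx(res.d_bar - res.d_hat)
        assert res.n_nonfinite_draws == 0

    def test_null_data_does_not_prefer_overparameterised_model(self):
        """Parsimony: with exchangeable cells the 6-cell drift model gains
        no decisive DIC advantage over the baseline in most replicates."""
        base = default_ground_truth("null", n_subjects=3)
        truth = base.__class__(
            v_mean=base.v_mean,
            t_mean=base.t_mean,
            beta0=base.beta0,
            beta1=base.beta1,
            v_sd=0.0,
            t_sd=0.0,
            n_subjects=3,
        )
        mcmc = {"n_draws": 700, "n_burn_in": 250, "n_chains": 1}
        wins = 0
        for rep in range(10):
            table = simulate_cohort(truth, seed=700 + rep)
            filtered, _ = behavior.filter_trials(table, "ddm")
            dics = {}
            for mid in (1, 2):
                s = fit_hierarchical(
                    SPECS[mid], filtered, mcmc={**mcmc, "seed": 10 * rep + mid}
                )
                dics[mid] = compute_dic(s, filtered).dic
            wins += dics[2] - dics[1] > -10.0
        assert wins >= 8


class TestPosteriorPredictive:
    def test_table_shape_and_correlation(self, quick_fit, small_cohort_filtered):
        ppc = hbayes.posterior_predictive(
            quick_fit, small_cohort_filtered["ddm"], n_rep=8, seed=1
        )
        n_subj = small_cohort_filtered["ddm"]["subject"].nunique()
        assert len(ppc) == n_subj * 6
        r = np.corrcoef(ppc["observed_rt_ms"], ppc["pred_rt_ms"])[0, 1]
        assert r >= 0.9

    def test_self_consistency_on_posterior_generated_data(
        self, quick_fit, small_cohort_filtered
    ):
        """Predictions track the analytic expected RTs at the posterior means.

        The unbiased two-boundary process has mean decision time
        (a / 2v) tanh(av / 2); feeding those expectations in as the
        observed data, the simulated predictions must fall on the diagonal.
        """
        data = small_cohort_filtered["ddm"].copy().reset_index(drop=True)
        arr = hbayes._prepare(data)
        base_v = quick_fit.subject_mean["v"]["base"]
        base_a = quick_fit.subject_mean["a"]["base"]
        slope_a = quick_fit.subject_mean["a"]["slope"]
        base_t = quick_fit.subject_mean["t"]["base"]
        expected_rt = np.empty(len(data))
        for i in range(len(data)):
            s, c, e = arr.subj[i], arr.cell[i], arr.epoch[i]
            a = base_a[s, 0] + slope_a[s, c] * e
            v = base_v[s, c]
            mean_td = a * a / 4.0 if abs(v) < 1e-8 else (a / (2 * v)) * np.tanh(a * v / 2.0)
            expected_rt[i] = (base_t[s, c] + mean_td) * 1000.0
        synth = data.assign(rt_ms=expected_rt, correct=1)
        ppc = hbayes.posterior_predictive(quick_fit, synth, n_rep=25, seed=7)
        r = np.corrcoef(ppc["observed_rt_ms"], ppc["pred_rt_ms"])[0, 1]
        assert r > 0.99


def test_null_truth_contrasts_are_calibrated():
    """Old-new drift contrasts on a null cohort: squared z-scores chi-square sized."""
    truth = default_ground_truth("null", n_subjects=6)
    table = simulate_cohort(truth, seed=88)
    filtered, _ = behavior.filter_trials(table, "ddm")
    s = fit_hierarchical(
        SPECS[8], filtered, mcmc={"n_draws": 900, "n_burn_in": 300, "n_chains": 1, "seed": 2}
    )
    g = s.group_draws
    z2 = 0.0
    for short in ("uni", "msv", "mst"):
        diff = g[f"v_mu[{short}:old]"] - g[f"v_mu[{short}:new]"]
        z2 += (diff.mean() / diff.std()) ** 2
    from scipy import stats

    assert z2 < stats.chi2.ppf(0.99, df=3)
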
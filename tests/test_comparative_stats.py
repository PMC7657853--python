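"""MCMC PGLS, stepping-stone marginal likelihoods, coevolution, RM-ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal, ttest_rel

from bacushape import comparative_stats as cs
from bacushape.comparative_stats import (CoevResult, MCMCSettings,
                                         SteppingStoneModel,
                                         coevolution_test, pgls_mcmc,
                                         rm_anova_gg, run_chains_median,
                                         stepping_stone_logml)
from bacushape.trait_sim import (simulate_bivariate_bm,
                                 simulate_regression_dataset,
                                 simulate_yule_tree)

FAST = MCMCSettings.fast()


class TestPGLS:
    def test_self_regression_is_perfect(self):
        tree = simulate_yule_tree(32, seed=0)
        df = simulate_regression_dataset(tree, [0.0], 0.0, 0.5, 1.0, seed=1)
        post = pgls_mcmc(tree, df["y"], pd.DataFrame({"x": df["y"]}),
                         settings=FAST, seed=2, compute_logml=False)
        assert post.mean["x"] == pytest.approx(1.0, abs=0.05)
        assert post.r2 > 0.99
        assert post.p_values["x"] == 0.0

    def test_slope_recovery_with_low_noise(self):
        tree = simulate_yule_tree(64, seed=3)
        df = simulate_regression_dataset(tree, [1.0], 0.3, 0.5, 0.02, seed=4)
        post = pgls_mcmc(tree, df["y"], df[["x1"]], settings=FAST, seed=5,
                         compute_logml=False)
        assert post.mean["x1"] == pytest.approx(1.0, abs=0.2)
        assert post.p_values["x1"] < 0.05
        lo, hi = post.ci95["x1"]
        assert lo < np.median(post.samples["x1"]) < hi

    def test_sample_count_matches_settings(self):
        tree = simulate_yule_tree(16, seed=6)
        df = simulate_regression_dataset(tree, [0.5], 0.0, 0.5, 0.1, seed=7)
        post = pgls_mcmc(tree, df["y"], df[["x1"]], settings=FAST, seed=8,
                         compute_logml=False)
        assert len(post.samples) == (FAST.iterations - FAST.burnin) \
            // FAST.thin

    def test_lambda_posterior_concentrates_on_brownian_data(self):
        tree = simulate_yule_tree(64, seed=9)
        hits = 0
        n_rep = 20
        for s in range(n_rep):
            df = simulate_regression_dataset(tree, [0.0], 0.0, 1.0, 1.0,
                                             seed=100 + s)
            post = pgls_mcmc(tree, df["y"], df[["x1"]], settings=FAST,
                             seed=s, compute_logml=False)
            if post.mean["lambda"] > 0.8:
                hits += 1
        assert hits >= 0.8 * n_rep

    def test_rank_deficient_design_rejected(self):
        tree = simulate_yule_tree(16, seed=10)
        df = simulate_regression_dataset(tree, [1.0], 0.0, 0.5, 0.1, seed=11)
        X = pd.DataFrame({"a": df["x1"], "b": 2 * df["x1"]})
        with pytest.raises(ValueError, match="rank"):
            pgls_mcmc(tree, df["y"], X, settings=FAST, compute_logml=False)

    def test_non_positive_traits_rejected_before_log(self):
        tree = simulate_yule_tree(8, seed=12)
        y = np.array([1.0, 2, 3, 4, 5, 6, 7, -1])
        with pytest.raises(ValueError, match="positive"):
            pgls_mcmc(tree, y, np.ones((8, 1)), already_log=False,
                      settings=FAST, compute_logml=False)

    def test_reproducible_under_seed(self):
        tree = simulate_yule_tree(16, seed=13)
        df = simulate_regression_dataset(tree, [1.0], 0.0, 0.5, 0.1, seed=14)
        a = pgls_mcmc(tree, df["y"], df[["x1"]], settings=FAST, seed=99,
                      compute_logml=False)
        b = pgls_mcmc(tree, df["y"], df[["x1"]], settings=FAST, seed=99,
                      compute_logml=False)
        pd.testing.assert_frame_equal(a.samples, b.samples)


class TestRunChainsMedian:
    def test_median_chain_returned(self, monkeypatch):
        logmls = {0: -10.0, 1000: -12.0, 2000: -11.0}

        def fake_pgls(seed=None, compute_logml=True, **kw):
            post = pytest.importorskip("bacushape.comparative_stats")
            from bacushape.comparative_stats import PGLSPosterior
            return PGLSPosterior([], pd.DataFrame(), pd.Series(dtype=float),
                                 pd.Series(dtype=float), {}, {}, 0.0,
                                 logmls[seed], 0, seed)

        monkeypatch.setattr(cs, "pgls_mcmc", fake_pgls)
        out = run_chains_median({}, n_chains=3, base_seed=0)
        assert out.log_marginal_lik == -11.0

    def test_five_chains_middle_rank(self, monkeypatch):
        logmls = {0: -3.0, 1000: -9.0, 2000: -5.0, 3000: -1.0, 4000: -7.0}

        def fake_pgls(seed=None, compute_logml=True, **kw):
            from bacushape.comparative_stats import PGLSPosterior
            return PGLSPosterior([], pd.DataFrame(), pd.Series(dtype=float),
                                 pd.Series(dtype=float), {}, {}, 0.0,
                                 logmls[seed], 0, seed)

        monkeypatch.setattr(cs, "pgls_mcmc", fake_pgls)
        out = run_chains_median({}, n_chains=5, base_seed=0)
        assert out.log_marginal_lik == -5.0

    def test_even_chain_count_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            run_chains_median({}, n_chains=2)

    def test_failed_chain_raises(self, monkeypatch):
        def fake_pgls(seed=None, compute_logml=True, **kw):
            from bacushape.comparative_stats import PGLSPosterior
            return PGLSPosterior([], pd.DataFrame(), pd.Series(dtype=float),
                                 pd.Series(dtype=float), {}, {}, 0.0,
                                 np.nan, 0, seed)

        monkeypatch.setattr(cs, "pgls_mcmc", fake_pgls)
        with pytest.raises(RuntimeError, match="chain"):
            run_chains_median({}, n_chains=3)


class _ConjugateNormal(SteppingStoneModel):
    """y_i ~ N(μ, 1) with μ ~ N(0, 1): marginal is N(0, I + 11')."""

    def __init__(self, y):
        self.y = y
        self.bounds = np.array([[-np.inf, np.inf]])

    def log_lik(self, th):
        return float(-0.5 * np.sum((self.y - th[0]) ** 2)
                     - self.y.size / 2 * np.log(2 * np.pi))

    def log_prior(self, th):
        return float(-0.5 * th[0] ** 2 - 0.5 * np.log(2 * np.pi))

    def sample_prior(self, rng):
        return rng.standard_normal(1)


class _FlatLikelihood(SteppingStoneModel):
    def __init__(self):
        self.bounds = np.array([[0.0, 1.0], [0.0, 1.0]])

    def log_lik(self, th):
        return 0.0


class TestSteppingStone:
    def test_conjugate_normal_mean_oracle(self):
        rng = np.random.default_rng(0)
        y = rng.normal(0.3, 1.0, 20)
        n = y.size
        exact = multivariate_normal.logpdf(y, np.zeros(n),
                                           np.eye(n) + np.ones((n, n)))
        est = stepping_stone_logml(_ConjugateNormal(y), n_stones=100,
                                   iters_per_stone=2000, seed=1)
        assert est == pytest.approx(exact, abs=0.1)

    def test_unit_likelihood_gives_zero_logml(self):
        est = stepping_stone_logml(_FlatLikelihood(), n_stones=10,
                                   iters_per_stone=100, seed=2)
        assert est == pytest.approx(0.0, abs=1e-9)

    def test_variance_shrinks_with_more_stones(self):
        rng = np.random.default_rng(3)
        y = rng.normal(0.0, 1.0, 10)
        ests = {k: [stepping_stone_logml(_ConjugateNormal(y), n_stones=k,
                                         iters_per_stone=80, seed=s)
                    for s in range(50)] for k in (30, 60)}
        assert np.std(ests[60], ddof=1) < np.std(ests[30], ddof=1)

    def test_invalid_stone_count(self):
        with pytest.raises(ValueError, match="n_stones"):
            stepping_stone_logml(_FlatLikelihood(), n_stones=0)


class TestCoevolution:
    def test_identical_traits_are_strongly_dependent(self):
        tree = simulate_yule_tree(32, seed=0)
        uv = simulate_bivariate_bm(tree, 0.0, seed=1)
        res = coevolution_test(tree, uv["u"], uv["u"] * 1.0,
                               settings=FAST, seed=2)
        assert res.category == "strong"
        assert res.logbf == pytest.approx(
            2 * (res.logml_dependent - res.logml_independent))

    def test_symmetric_in_trait_order(self):
        tree = simulate_yule_tree(48, seed=3)
        uv = simulate_bivariate_bm(tree, 0.7, seed=4)
        mid = MCMCSettings(n_stones=60, iters_per_stone=800)
        a = coevolution_test(tree, uv["u"], uv["v"], settings=mid, seed=5)
        b = coevolution_test(tree, uv["v"], uv["u"], settings=mid, seed=105)
        # identical by construction up to Monte-Carlo error of the sampler
        assert abs(a.logbf - b.logbf) < 2.0

    def test_independent_logml_is_sum_of_univariate(self):
        """Additivity: a diagonal bivariate model factorizes, so its logML
        must equal the sum of the two univariate Brownian logMLs."""
        tree = simulate_yule_tree(24, seed=7)
        uv = simulate_bivariate_bm(tree, 0.0, seed=8)

        class _UniBM(SteppingStoneModel):
            def __init__(self, biv, which):
                self.biv = biv
                self.which = which
                idx = [0, 2] if which == 0 else [1, 3]
                self.bounds = biv.bounds[idx]

            def log_lik(self, th):
                full = np.array([th[0], th[0], th[1], th[1]])
                if self.which == 0:
                    other = self.biv.vw
                    # evaluate only the u-margin: reconstruct from bivariate
                g = self.biv.g
                data = self.biv.uw if self.which == 0 else self.biv.vw
                s = np.exp(th[1])
                r = data - th[0] * g
                return float(-0.5 * (np.sum(r * r) / s
                                     + data.size * (np.log(s)
                                                    + np.log(2 * np.pi))))

        ind = cs._BivariateBMModel(tree, uv["u"].to_numpy(),
                                   uv["v"].to_numpy(), dependent=False)
        lm_ind = stepping_stone_logml(ind, 40, 600, seed=9)
        lm_u = stepping_stone_logml(_UniBM(ind, 0), 40, 600, seed=10)
        lm_v = stepping_stone_logml(_UniBM(ind, 1), 40, 600, seed=11)
        assert lm_ind == pytest.approx(lm_u + lm_v, abs=1.0)

    def test_too_few_complete_pairs(self):
        tree = simulate_yule_tree(8, seed=12)
        u = pd.Series(np.arange(8.0), index=tree.tip_labels)
        v = u.copy()
        v.iloc[:5] = np.nan
        with pytest.raises(ValueError, match="complete"):
            coevolution_test(tree, u, v)

    def test_categories(self):
        assert CoevResult.categorize(-1.0) == "independent"
        assert CoevResult.categorize(1.0) == "weak"
        assert CoevResult.categorize(3.0) == "positive"
        assert CoevResult.categorize(6.0) == "strong"


class TestRMAnova:
    def test_compound_symmetry_gives_epsilon_near_one(self, rng):
        n, k = 200, 4
        subj = rng.normal(0, 1.0, size=(n, 1))
        Y = subj + rng.normal(0, 1.0, size=(n, k))
        res = rm_anova_gg(Y)
        assert res.gg_epsilon > 0.95

    def test_epsilon_lower_bound_k3(self, rng):
        # heavily non-spherical: third condition nearly duplicates second
        Y = rng.normal(size=(30, 2))
        Y = np.column_stack([Y[:, 0], Y[:, 1], Y[:, 1] + 1e-6 *
                             rng.normal(size=30)])
        res = rm_anova_gg(Y)
        assert res.gg_epsilon >= 0.5 - 1e-12

    def test_matches_frozen_worked_example(self):
        """8×3 fixture; expected values computed independently with the
        textbook sums-of-squares / contrast-covariance formulas."""
        Y = np.array([
            [5.1, 6.2, 7.1], [4.8, 5.9, 6.4], [5.5, 6.8, 7.9],
            [5.0, 6.0, 6.8], [4.2, 5.1, 6.0], [5.9, 7.2, 8.5],
            [5.3, 6.1, 7.3], [4.6, 5.4, 6.1]])
        res = rm_anova_gg(Y)
        # frozen oracle values (independent spreadsheet-style computation:
        # sums of squares, normalized-contrast covariance eigenvalues)
        assert res.f_stat == pytest.approx(182.72073342736257, abs=1e-6)
        assert res.gg_epsilon == pytest.approx(0.6573244692953667, abs=1e-6)
        assert res.mauchly_w == pytest.approx(0.4786813108114297, abs=1e-6)

    def test_agrees_with_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        Y = rng.normal(size=(25, 3)) + np.array([0.0, 0.4, 0.1])
        res = rm_anova_gg(Y)
        n, k = Y.shape
        long = pd.DataFrame({
            "y": Y.ravel(),
            "cond": np.tile(np.arange(k), n),
            "subj": np.repeat(np.arange(n), k)})
        tab = pg.rm_anova(long, dv="y", within="cond", subject="subj",
                          correction=True)
        assert res.f_stat == pytest.approx(float(tab["F"].iloc[0]), rel=1e-9)
        assert res.gg_epsilon == pytest.approx(float(tab["eps"].iloc[0]),
                                               rel=1e-9)
        assert res.p_value == pytest.approx(float(tab["p_GG_corr"].iloc[0]),
                                            rel=1e-6)
        sph = pg.sphericity(long, dv="y", within="cond", subject="subj")
        assert res.mauchly_w == pytest.approx(float(sph.W), rel=1e-9)
        assert res.mauchly_p == pytest.approx(float(sph.pval), rel=1e-6)

    def test_two_conditions_reduce_to_paired_t(self, rng):
        Y = rng.normal(size=(15, 2)) + np.array([0.0, 0.5])
        res = rm_anova_gg(Y)
        t, p = ttest_rel(Y[:, 0], Y[:, 1])
        assert res.f_stat == pytest.approx(t ** 2, abs=1e-9)
        assert res.gg_epsilon == pytest.approx(1.0)

    def test_insufficient_subjects(self, rng):
        with pytest.raises(ValueError, match="insufficient"):
            rm_anova_gg(rng.normal(size=(2, 3)))

    def test_pairwise_bonferroni(self, rng):
        Y = rng.normal(size=(40, 3))
        Y[:, 2] += 2.0
        res = rm_anova_gg(Y)
        assert res.pairwise_p[(0, 2)] < 0.001
        assert res.pairwise_p[(1, 2)] < 0.001
        assert res.pairwise_p[(0, 1)] > 0.05
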
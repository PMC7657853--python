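"""Phylogenetic signal, ancestral states, Mk/simmap, regime models, AICc."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm
from scipy.stats import kstest, multivariate_normal

from bacushape.phylo_models import (ModelFit, _PaintedDesign, aicc,
                                    akaike_weights, ancestral_states_bm,
                                    fit_mk, fit_trait_model, model_select,
                                    pagel_lambda, sample_stochastic_maps)
from bacushape.trait_sim import (simulate_discrete_history,
                                 simulate_regression_dataset, simulate_trait,
                                 simulate_yule_tree)
from bacushape.trees import Phylogeny, RegimePaintedTree


def _sym_Q(rate, k=2):
    return rate * (np.ones((k, k)) - k * np.eye(k)) / (k - 1)


class TestPagelLambda:
    def test_brownian_data_recovers_high_lambda(self):
        tree = simulate_yule_tree(64, seed=0)
        lams = []
        for s in range(100):
            df = simulate_regression_dataset(tree, [0.0], 0.0, 1.0, 1.0,
                                             seed=s)
            lams.append(pagel_lambda(tree, df["y"]).lam)
        assert np.median(lams) > 0.9

    def test_iid_data_recovers_low_lambda(self):
        tree = simulate_yule_tree(64, seed=1)
        lams = [pagel_lambda(
            tree, simulate_regression_dataset(tree, [0.0], 0.0, 0.0, 1.0,
                                              seed=s)["y"]).lam
            for s in range(100)]
        assert np.median(lams) < 0.1

    def test_null_lrt_p_uniform_on_interior(self):
        """Under λ=0, interior LRT p-values (λ̂ off the boundary) are U(0,1);
        the boundary mass at p=1 is excluded before the KS test."""
        tree = simulate_yule_tree(32, seed=2)
        ps = []
        for s in range(500):
            df = simulate_regression_dataset(tree, [0.0], 0.0, 0.0, 1.0,
                                             seed=s)
            fit = pagel_lambda(tree, df["y"])
            if fit.lrt > 1e-10:
                ps.append(fit.p_value)
        stat, p = kstest(ps, "uniform")
        assert p > 0.01

    def test_loglik_matches_dense_mvn_oracle(self, balanced8):
        rng = np.random.default_rng(3)
        x = rng.normal(size=8)
        fit = pagel_lambda(balanced8, x)
        C = balanced8.vcv()
        lam = fit.lam
        V = lam * C + (1 - lam) * np.diag(np.diag(C))
        oracle = multivariate_normal.logpdf(
            x, np.full(8, fit.mean), fit.sigma2 * V)
        assert fit.loglik == pytest.approx(oracle, abs=1e-6)

    def test_constant_trait_rejected(self, balanced8):
        with pytest.raises(ValueError, match="variance"):
            pagel_lambda(balanced8, np.ones(8))


class TestAncestralStates:
    def test_two_tip_inverse_variance_weighting(self, two_tip):
        x = pd.Series([1.0, 3.0], index=["A", "B"])
        t1, t2 = 0.4, 0.9
        expected = (1.0 / t1 + 3.0 / t2) / (1 / t1 + 1 / t2)
        anc = ancestral_states_bm(two_tip, x)
        assert anc.iloc[0] == pytest.approx(expected)

    def test_star_tree_gives_arithmetic_mean(self):
        star = Phylogeny.from_newick("(A:1,B:1,C:1,D:1,E:1);")
        x = np.array([2.0, 4.0, 6.0, 1.0, 7.0])
        anc = ancestral_states_bm(star, x)
        assert anc.iloc[0] == pytest.approx(x.mean())

    def test_matches_joint_gls_oracle_on_16_tips(self):
        """Brute force: build the joint (tips+nodes) BM covariance from
        path lengths and condition the Gaussian directly."""
        tree = simulate_yule_tree(16, seed=5)
        rng = np.random.default_rng(6)
        x = rng.normal(size=16)
        anc = ancestral_states_bm(tree, x)
        # joint covariance via shared path lengths for all node pairs
        n_all = tree.n_nodes
        anc_paths = []
        for v in range(n_all):
            path, u = set(), v
            while u >= 0:
                path.add(u)
                u = tree.parent[u]
            anc_paths.append(path)
        Cfull = np.zeros((n_all, n_all))
        for u in range(n_all):
            for v in range(n_all):
                shared = anc_paths[u] & anc_paths[v]
                Cfull[u, v] = max(tree.node_height[w] for w in shared)
        tips = np.arange(16)
        internal = np.array([v for v in range(n_all) if tree.children[v]])
        Ctt = Cfull[np.ix_(tips, tips)]
        Cnt = Cfull[np.ix_(internal, tips)]
        one = np.ones(16)
        Cinv = np.linalg.inv(Ctt)
        mu = (one @ Cinv @ x) / (one @ Cinv @ one)
        oracle = mu + Cnt @ Cinv @ (x - mu)
        np.testing.assert_allclose(anc.to_numpy(), oracle, atol=1e-8)


class TestMkFit:
    def test_rate_recovery_within_20_percent(self):
        tree = simulate_yule_tree(96, seed=7)
        r_hats = []
        for s in range(12):
            pt = simulate_discrete_history(tree, _sym_Q(1.0), seed=s)
            if len(set(pt.tip_states())) < 2:
                continue
            fit = fit_mk(tree, pt.tip_states(), "SYM")
            r_hats.append(fit.Q[0, 1])
        assert abs(np.median(r_hats) - 1.0) < 0.2

    def test_ml_dominates_true_rate_matrix(self, balanced8):
        from bacushape.phylo_models import _mk_loglik, _encode_states
        Q = _sym_Q(0.8)
        pt = simulate_discrete_history(balanced8, Q, seed=11)
        if len(set(pt.tip_states())) < 2:
            pytest.skip("degenerate draw")
        fit = fit_mk(balanced8, pt.tip_states(), "SYM")
        _, tips = _encode_states(balanced8, pt.tip_states())
        ll_true = _mk_loglik(balanced8, tips, Q, fit.root_freqs)
        assert fit.loglik >= ll_true - 1e-6

    def test_low_change_pattern_drives_rate_toward_zero(self):
        # a perfectly clade-sorted pattern needs only one change
        quartet = Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        states = pd.Series(["x", "x", "y", "y"],
                           index=["A", "B", "C", "D"])
        fit = fit_mk(quartet, states, "SYM")
        # one change on total length 6 → ML rate well below 1 change/branch
        assert fit.Q[0, 1] < 0.5
        from bacushape.phylo_models import _encode_states, _mk_build_Q, \
            _mk_loglik
        _, tips = _encode_states(quartet, states)
        for r in (1e-6, 2.0):
            alt = _mk_loglik(quartet, tips, _mk_build_Q(np.array([r]), 2,
                                                        "SYM"),
                             fit.root_freqs)
            assert fit.loglik > alt

    def test_single_observed_state_rejected(self, balanced8):
        with pytest.raises(ValueError, match="2 observed states"):
            fit_mk(balanced8, ["a"] * 8)


class TestStochasticMaps:
    def test_zero_rate_maps_have_no_transitions(self, balanced8):
        from bacushape.phylo_models import MkFit
        mk = MkFit(np.zeros((2, 2)), "SYM", 0.0, np.array([1.0, 0.0]),
                   ["a", "b"])
        maps = sample_stochastic_maps(balanced8, ["a"] * 8, mk, n_maps=5,
                                      seed=0)
        assert all(m.n_transitions() == 0 for m in maps)

    def test_root_state_posterior_matches_enumeration(self, two_tip):
        """2-tip, 2-state: the sampled root-state frequency must match the
        exact conditional posterior computed by enumeration over states."""
        from bacushape.phylo_models import MkFit
        Q = np.array([[-0.9, 0.9], [0.4, -0.4]])
        pi = np.array([0.5, 0.5])
        mk = MkFit(Q, "ARD", 0.0, pi, ["a", "b"])
        tips = pd.Series(["a", "b"], index=["A", "B"])
        # exact: P(root=r | tips) ∝ π_r · P_{r,a}(0.4) · P_{r,b}(0.9)
        Pa, Pb = expm(Q * 0.4), expm(Q * 0.9)
        w = pi * Pa[:, 0] * Pb[:, 1]
        exact = w[0] / w.sum()
        n = 5000
        maps = sample_stochastic_maps(two_tip, tips, mk, n_maps=n, seed=1)
        freq = np.mean([m.root_state == 0 for m in maps])
        se = np.sqrt(exact * (1 - exact) / n)
        assert abs(freq - exact) < 3 * se

    def test_transition_count_monotone_in_rate(self, balanced8):
        from bacushape.phylo_models import MkFit
        tips = pd.Series(list("aabbaabb"), index=list("ABCDEFGH"))
        means = []
        for rate in (0.2, 1.0, 5.0):
            mk = MkFit(_sym_Q(rate), "SYM", 0.0, np.array([0.5, 0.5]),
                       ["a", "b"])
            maps = sample_stochastic_maps(balanced8, tips, mk, n_maps=200,
                                          seed=2)
            means.append(np.mean([m.n_transitions() for m in maps]))
        assert means[0] < means[1] < means[2]

    def test_invalid_map_count(self, balanced8):
        from bacushape.phylo_models import MkFit
        mk = MkFit(_sym_Q(1.0), "SYM", 0.0, np.array([0.5, 0.5]),
                   ["a", "b"])
        with pytest.raises(ValueError, match="n_maps"):
            sample_stochastic_maps(balanced8, list("aabbaabb"), mk, n_maps=0)


def _painted_on(tree, rate=0.8, k=2, seed=0):
    pt = simulate_discrete_history(tree, _sym_Q(rate, k), seed=seed)
    while len(set(pt.tip_states())) < k:
        seed += 1
        pt = simulate_discrete_history(tree, _sym_Q(rate, k), seed=seed)
    return pt


class TestTraitModels:
    def test_bm1_loglik_matches_dense_mvn(self):
        tree = Phylogeny.from_newick(
            "((A:0.3,B:0.3):0.7,((C:0.4,D:0.4):0.2,E:0.6):0.4,F:1.0);")
        pt = _painted_on(tree, seed=3)
        rng = np.random.default_rng(4)
        x = rng.normal(size=6)
        design = _PaintedDesign(pt)
        sig2, root = 0.7, 0.2
        mine = design.cov_bm1(sig2)
        oracle = multivariate_normal.logpdf(x, np.full(6, root),
                                            sig2 * tree.vcv())
        from bacushape.phylo_models import _mvn_loglik
        assert _mvn_loglik(x, np.full(6, root), mine) == \
            pytest.approx(oracle, abs=1e-6)

    def test_ou_limit_recovers_brownian_likelihood(self, balanced8):
        pt = _painted_on(balanced8, seed=5)
        rng = np.random.default_rng(6)
        x = rng.normal(size=8)
        design = _PaintedDesign(pt)
        from bacushape.phylo_models import _mvn_loglik
        sig2, theta = 0.9, 0.3
        mean, C = design.ou_moments(1e-8, np.full(2, sig2),
                                    np.full(2, theta))
        ll_ou = _mvn_loglik(x, mean, C)
        ll_bm = _mvn_loglik(x, np.full(8, theta), design.cov_bm1(sig2))
        assert ll_ou == pytest.approx(ll_bm, abs=1e-4)

    def test_bms_covariance_integrates_regime_time(self, balanced8):
        pt = _painted_on(balanced8, seed=7)
        design = _PaintedDesign(pt)
        sig2 = np.array([0.5, 2.0])
        C = design.cov_bms(sig2)
        # diagonal: per-tip integral of σ²(regime) along its root path
        S = pt.regime_time_to_node()[: balanced8.n_tips]
        np.testing.assert_allclose(np.diag(C), S @ sig2)
        # setting both rates equal reduces to BM1
        np.testing.assert_allclose(design.cov_bms(np.array([0.7, 0.7])),
                                   design.cov_bm1(0.7), atol=1e-12)

    def test_oum_theta_recovery(self):
        """Median optimum-estimate error < 0.25 over replicate simulations
        (strong pull a=5, two regimes at 0 and 2, 128 tips)."""
        tree = simulate_yule_tree(128, seed=8)
        pt = _painted_on(tree, seed=9)
        errs = []
        for s in range(20):
            x = simulate_trait(pt, "OUM",
                               dict(root=0.0, alpha=5.0, sigma2=0.5,
                                    theta=np.array([0.0, 2.0])), seed=s)
            fit = fit_trait_model(pt, x, "OUM", seed=s)
            errs.append(np.abs(fit.params["theta"]
                               - np.array([0.0, 2.0])).max())
        assert np.median(errs) < 0.25

    def test_missing_regime_raises(self, balanced8):
        segs = [[(0, bl)] if bl > 0 else []
                for bl in balanced8.edge_length]
        pt = RegimePaintedTree(balanced8, segs, 0, ["GL", "S"])
        with pytest.raises(ValueError, match="absent"):
            fit_trait_model(pt, np.arange(8.0), "OUM")

    def test_hessian_flags_boolean_and_k_counts(self, balanced8):
        pt = _painted_on(balanced8, seed=10)
        x = simulate_trait(pt, "BM1", dict(root=0.0, sigma2=0.5), seed=1)
        expect_k = {"BM1": 2, "BMS": 3, "OU1": 3, "OUM": 4, "OUMV": 5}
        for model, k in expect_k.items():
            fit = fit_trait_model(pt, x, model, n_starts=2, seed=2)
            assert fit.k == k
            assert isinstance(fit.hessian_ok, bool)
            assert fit.aicc == pytest.approx(aicc(fit.loglik, k, 8))


class TestModelSelect:
    def test_printed_aicc_table_weights(self):
        w = akaike_weights({"BM1": 61.8, "BMS": 13.2, "OU1": 37.3,
                            "OUM": 36.2, "OUMV": 12.7})
        assert round(w["BM1"], 2) == 0.00
        assert round(w["BMS"], 2) == 0.44
        assert round(w["OU1"], 2) == 0.00
        assert round(w["OUM"], 2) == 0.00
        assert round(w["OUMV"], 2) == 0.56

    def test_equal_aicc_splits_weight(self):
        w = akaike_weights({"a": 10.0, "b": 10.0, "c": 300.0})
        assert w["a"] == pytest.approx(0.5, abs=1e-6)
        assert w["b"] == pytest.approx(0.5, abs=1e-6)

    def test_aicc_formula(self):
        assert aicc(0.0, 1, 100) == pytest.approx(2 + 4 / 98)

    def test_invalid_fits_discarded_and_weights_renormalize(self):
        def mk_fit(model, a, ok=True):
            return ModelFit(model, 0.0, {}, 2, 20, a, ok, ok, True)
        fits = [{"BM1": mk_fit("BM1", 10.0),
                 "OU1": mk_fit("OU1", 10.0),
                 "OUM": mk_fit("OUM", 5.0, ok=False)}]
        sel = model_select(fits, models=("BM1", "OU1", "OUM"))
        tab = sel.table.set_index("model")
        assert tab.loc["OUM", "n_valid"] == 0
        assert np.isnan(tab.loc["OUM", "mean_aicc"])
        assert tab.loc["BM1", "weight"] == pytest.approx(0.5, abs=1e-9)
        valid_w = tab["weight"].dropna().sum()
        assert valid_w == pytest.approx(1.0, abs=1e-9)

    def test_per_map_tally_and_within_two(self):
        def mk_fit(model, a):
            return ModelFit(model, 0.0, {}, 2, 20, a, True, True, True)
        fits = [{"BMS": mk_fit("BMS", 10.0), "OUMV": mk_fit("OUMV", 11.0)},
                {"BMS": mk_fit("BMS", 12.0), "OUMV": mk_fit("OUMV", 7.0)}]
        sel = model_select(fits, models=("BMS", "OUMV"))
        assert sel.best_tally == {"BMS": 1, "OUMV": 1}
        assert sel.frac_second_within_2 == pytest.approx(0.5)
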
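"""Phylogenetic signal, ancestral states, Mk/simmap, and BM/OU regime models.

The continuous-trait machinery treats every model as a multivariate normal
over tip values whose mean and covariance are implied by the tree and, for
multi-regime models, by a regime painting of its branches:

* ``BM1``   — single diffusion rate σ²; covariance σ²·(shared path time).
* ``BMS``   — per-regime σ²; covariance integrates σ²(regime) over the
  shared root→MRCA path.
* ``OU1/OUM/OUMV`` — Ornstein–Uhlenbeck pull ``a`` toward optima θ (global,
  per-regime, or per-regime with per-regime σ²).  The root starts at the
  root-regime optimum with zero variance, so the a→0 limit recovers Brownian
  motion exactly.

Model support is compared by small-sample AICc with Akaike weights, after
discarding fits whose numerical Hessian is not positive definite or whose
optima fall an order of magnitude outside the observed trait range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, expm
from scipy.stats import chi2

from .trees import Phylogeny, RegimePaintedTree
from .trait_sim import lambda_cov

__all__ = [
    "LambdaFit", "MkFit", "ModelFit", "ModelSelectionTable",
    "pagel_lambda", "ancestral_states_bm", "fit_mk",
    "sample_stochastic_maps", "fit_trait_model", "model_select", "aicc",
]

ALPHA_MAX = 100.0          # OU pull bound on unit-height trees


# ---------------------------------------------------------------------------
# MVN helpers

def _mvn_loglik(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    n = x.size
    try:
        c, low = cho_factor(cov, check_finite=False)
    except np.linalg.LinAlgError:
        return -np.inf
    r = x - mean
    alpha = cho_solve((c, low), r, check_finite=False)
    logdet = 2.0 * np.log(np.diag(c)).sum()
    return float(-0.5 * (n * np.log(2 * np.pi) + logdet + r @ alpha))


def _profile_mean_sigma(x: np.ndarray, corr: np.ndarray):
    """ML mean and scale for cov = σ²·corr; returns (μ̂, σ̂², lnL)."""
    n = x.size
    c, low = cho_factor(corr, check_finite=False)
    one = np.ones(n)
    ci_one = cho_solve((c, low), one, check_finite=False)
    ci_x = cho_solve((c, low), x, check_finite=False)
    mu = (one @ ci_x) / (one @ ci_one)
    r = x - mu
    sig2 = float(r @ cho_solve((c, low), r, check_finite=False)) / n
    logdet = 2.0 * np.log(np.diag(c)).sum()
    lnl = -0.5 * (n * np.log(2 * np.pi * sig2) + logdet + n)
    return float(mu), sig2, float(lnl)


# ---------------------------------------------------------------------------
# Pagel's lambda

@dataclass
class LambdaFit:
    lam: float
    loglik: float
    loglik0: float
    lrt: float
    p_value: float
    sigma2: float
    mean: float

    def to_dict(self) -> dict:
        return {"lambda": self.lam, "loglik": self.loglik,
                "loglik0": self.loglik0, "lrt": self.lrt, "p": self.p_value,
                "sigma2": self.sigma2, "mean": self.mean}


def pagel_lambda(tree: Phylogeny, trait: pd.Series | np.ndarray) -> LambdaFit:
    """ML Pagel's λ with a likelihood-ratio test against λ = 0.

    λ multiplies the off-diagonal phylogenetic covariances; the Brownian
    rate σ² and the root mean are profiled out analytically, leaving a 1-D
    bounded likelihood maximization on λ ∈ [0, 1].  The test statistic
    2·(lnL(λ̂) − lnL(0)) is referred to χ² with 1 df.
    """
    x = _align_trait(tree, trait)
    if x.size < 4:
        raise ValueError("need at least 4 tips with trait values")
    if np.ptp(x) == 0:
        raise ValueError("trait has no variance")

    def nll(lam: float) -> float:
        return -_profile_mean_sigma(x, lambda_cov(tree, lam))[2]

    res = optimize.minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded",
                                   options={"xatol": 1e-8})
    lam = float(res.x)
    # the boundary can beat the interior optimum found by Brent
    cands = [(nll(0.0), 0.0), (nll(1.0), 1.0), (res.fun, lam)]
    best_nll, lam = min(cands)
    mu, sig2, lnl = _profile_mean_sigma(x, lambda_cov(tree, lam))
    lnl0 = -nll(0.0)
    lrt = max(0.0, 2.0 * (lnl - lnl0))
    return LambdaFit(lam, lnl, lnl0, lrt, float(chi2.sf(lrt, df=1)),
                     sig2, mu)


def _align_trait(tree: Phylogeny, trait) -> np.ndarray:
    if isinstance(trait, pd.Series):
        missing = [t for t in tree.tip_labels if t not in trait.index]
        if missing:
            raise ValueError(f"trait missing for tips {missing[:5]}")
        return trait.reindex(tree.tip_labels).to_numpy(dtype=float)
    x = np.asarray(trait, dtype=float)
    if x.size != tree.n_tips:
        raise ValueError("trait length does not match tip count")
    return x


# ---------------------------------------------------------------------------
# ancestral states (ML / GLS under BM)

def ancestral_states_bm(tree: Phylogeny, trait) -> pd.Series:
    """ML ancestral values at internal nodes under Brownian motion.

    Generalized-least-squares conditional expectations: the root takes the
    GLS mean, every other internal node the BM conditional expectation given
    the tips.  On a two-tip tree this is the inverse-variance-weighted tip
    average; on a star tree the arithmetic mean.
    """
    x = _align_trait(tree, trait)
    if np.ptp(x) == 0:
        raise ValueError("trait has no variance")
    n = tree.n_tips
    C = tree.vcv()
    mu, _, _ = _profile_mean_sigma(x, C)
    internal = [v for v in range(tree.n_nodes) if tree.children[v]]
    # cross-covariance: height of mrca(node, tip)
    anc_sets = _ancestor_sets(tree)
    A = np.empty((len(internal), n))
    for r_i, v in enumerate(internal):
        for i in range(n):
            A[r_i, i] = tree.node_height[_mrca_pair(tree, anc_sets, v, i)]
    c, low = cho_factor(C, check_finite=False)
    est = mu + A @ cho_solve((c, low), x - mu, check_finite=False)
    return pd.Series(est, index=[f"node{v}" for v in internal])


def _ancestor_sets(tree: Phylogeny) -> list[list[int]]:
    out: list[list[int]] = [[] for _ in range(tree.n_nodes)]
    for v in tree.postorder[::-1]:
        p = tree.parent[v]
        out[v] = ([v] + out[p]) if p >= 0 else [v]
    return out


def _mrca_pair(tree: Phylogeny, anc: list[list[int]], u: int, v: int) -> int:
    su = set(anc[u])
    for w in anc[v]:
        if w in su:
            return w
    return tree.root


# ---------------------------------------------------------------------------
# Mk models and stochastic character maps

@dataclass
class MkFit:
    Q: np.ndarray
    model_form: str             # ER | SYM | ARD
    loglik: float
    root_freqs: np.ndarray
    states: list[str]
    converged: bool = True


def _mk_build_Q(rates: np.ndarray, k: int, form: str) -> np.ndarray:
    Q = np.zeros((k, k))
    if form == "ER":
        Q[:] = rates[0]
    elif form == "SYM":
        iu = np.triu_indices(k, 1)
        Q[iu] = rates
        Q.T[iu] = rates
    elif form == "ARD":
        mask = ~np.eye(k, dtype=bool)
        Q[mask] = rates
    else:
        raise ValueError(f"unknown Mk form {form!r}")
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _mk_n_rates(k: int, form: str) -> int:
    return {"ER": 1, "SYM": k * (k - 1) // 2, "ARD": k * (k - 1)}[form]


def _mk_loglik(tree: Phylogeny, tips: np.ndarray, Q: np.ndarray,
               root_freqs: np.ndarray,
               return_partials: bool = False):
    """Felsenstein pruning; optionally returns per-node partials and P's."""
    k = Q.shape[0]
    L = np.zeros((tree.n_nodes, k))
    P = [None] * tree.n_nodes
    for v in range(tree.n_tips):
        L[v, tips[v]] = 1.0
    scale = 0.0
    for v in tree.postorder:
        if v != tree.root:
            P[v] = expm(Q * tree.edge_length[v])
        if tree.children[v]:
            L[v] = 1.0
            for c in tree.children[v]:
                L[v] *= P[c] @ L[c]
            s = L[v].sum()
            if s <= 0:
                return (-np.inf, L, P) if return_partials else -np.inf
            L[v] /= s
            scale += np.log(s)
    lik = float(root_freqs @ L[tree.root])
    ll = np.log(lik) + scale if lik > 0 else -np.inf
    return (ll, L, P) if return_partials else ll


def fit_mk(tree: Phylogeny, tip_states, model_form: str = "SYM",
           root: str = "equal") -> MkFit:
    """ML continuous-time Markov (Mk) fit for a discrete tip character.

    ``model_form``: ``ER`` (one rate), ``SYM`` (symmetric rates, the
    stochastic-mapping default) or ``ARD`` (all rates different).  Root
    frequencies: ``equal`` (default) or ``stationary``.
    """
    states, tips = _encode_states(tree, tip_states)
    k = len(states)
    if k < 2:
        raise ValueError("need at least 2 observed states")
    n_rates = _mk_n_rates(k, model_form)
    root_freqs = np.full(k, 1.0 / k)

    def nll(log_rates: np.ndarray) -> float:
        Q = _mk_build_Q(np.exp(log_rates), k, model_form)
        return -_mk_loglik(tree, tips, Q, root_freqs)

    total = tree.tree_length
    best = None
    for r0 in (1.0 / total * k, 5.0 / total, 0.2 / total):
        res = optimize.minimize(nll, np.full(n_rates, np.log(r0)),
                                method="L-BFGS-B",
                                bounds=[(-18.0, 12.0)] * n_rates)
        if best is None or res.fun < best.fun:
            best = res
    Q = _mk_build_Q(np.exp(best.x), k, model_form)
    if root == "stationary":
        # stationary distribution of Q
        w, v = np.linalg.eig(Q.T)
        pi = np.real(v[:, np.argmin(np.abs(w))])
        root_freqs = np.abs(pi) / np.abs(pi).sum()
    return MkFit(Q, model_form, -float(best.fun), root_freqs, states,
                 converged=bool(best.success))


def _encode_states(tree: Phylogeny, tip_states):
    if isinstance(tip_states, pd.Series):
        tip_states = tip_states.reindex(tree.tip_labels)
        vals = tip_states.to_list()
    else:
        vals = list(tip_states)
    if len(vals) != tree.n_tips:
        raise ValueError("tip state length does not match tip count")
    states = sorted({str(v) for v in vals})
    idx = {s: i for i, s in enumerate(states)}
    return states, np.array([idx[str(v)] for v in vals], dtype=int)


def sample_stochastic_maps(tree: Phylogeny, tip_states, mkfit: MkFit,
                           n_maps: int = 1, seed: int | None = None
                           ) -> list[RegimePaintedTree]:
    """Stochastic character maps conditional on the tips and a fitted Mk model.

    Node states are sampled root-down from their conditional distributions;
    within-branch histories conditional on both endpoints are drawn by
    uniformization (jump-count then jump-chain sampling).
    """
    if n_maps < 1:
        raise ValueError("n_maps must be ≥ 1")
    states = mkfit.states
    if isinstance(tip_states, pd.Series):
        vals = tip_states.reindex(tree.tip_labels).to_list()
    else:
        vals = list(tip_states)
    idx = {s: i for i, s in enumerate(states)}
    try:
        tips = np.array([idx[str(v)] for v in vals], dtype=int)
    except KeyError as e:
        raise ValueError(f"tip state {e} not in the fitted Mk alphabet")
    Q = mkfit.Q
    k = Q.shape[0]
    rng = np.random.default_rng(seed)
    _, L, P = _mk_loglik(tree, tips, Q, mkfit.root_freqs, return_partials=True)
    mu = max(float(np.max(-np.diag(Q))), 1e-12)
    R = np.eye(k) + Q / mu
    Rpow = [np.eye(k), R]

    def rpow(n: int) -> np.ndarray:
        while len(Rpow) <= n:
            Rpow.append(Rpow[-1] @ R)
        return Rpow[n]

    maps: list[RegimePaintedTree] = []
    for _ in range(n_maps):
        node_state = np.empty(tree.n_nodes, dtype=int)
        w = mkfit.root_freqs * L[tree.root]
        node_state[tree.root] = rng.choice(k, p=w / w.sum())
        for v in tree.postorder[::-1]:
            if v == tree.root:
                continue
            i = node_state[tree.parent[v]]
            w = P[v][i] * L[v]
            node_state[v] = rng.choice(k, p=w / w.sum())
        segments: list[list[tuple[int, float]]] = [[] for _ in
                                                   range(tree.n_nodes)]
        for v in range(tree.n_nodes):
            if v == tree.root:
                continue
            i, j = node_state[tree.parent[v]], node_state[v]
            segments[v] = _sample_branch_path(
                i, j, float(tree.edge_length[v]), Q, mu, rpow,
                float(P[v][i, j]), rng)
        maps.append(RegimePaintedTree(tree, segments,
                                      int(node_state[tree.root]), states))
    return maps


def _sample_branch_path(i: int, j: int, t: float, Q: np.ndarray, mu: float,
                        rpow, p_ij: float, rng: np.random.Generator
                        ) -> list[tuple[int, float]]:
    """Endpoint-conditioned CTMC path by uniformization."""
    if t <= 0:
        return [(j, 0.0)] if i == j else [(j, 0.0)]
    # sample number of (possibly virtual) jumps
    u = rng.uniform() * p_ij
    acc = 0.0
    n = -1
    log_pois = -mu * t
    pois = np.exp(log_pois)
    while acc < u and n < 10_000:
        n += 1
        if n > 0:
            pois *= mu * t / n
        acc += pois * rpow(n)[i, j]
    if n <= 0:
        return [(i, t)]
    times = np.sort(rng.uniform(0.0, t, size=n))
    # jump chain conditioned on endpoint
    seq = [i]
    for m in range(1, n + 1):
        prev = seq[-1]
        w = rpow(1)[prev] * rpow(n - m)[:, j]
        seq.append(int(rng.choice(Q.shape[0], p=w / w.sum())))
    # collapse virtual (self) jumps into segments
    segs: list[tuple[int, float]] = []
    bounds = np.concatenate([[0.0], times, [t]])
    cur_state, cur_start = seq[0], 0.0
    for m in range(1, n + 1):
        if seq[m] != cur_state:
            segs.append((cur_state, float(times[m - 1] - cur_start)))
            cur_state, cur_start = seq[m], float(times[m - 1])
    segs.append((cur_state, float(t - cur_start)))
    return segs


# ---------------------------------------------------------------------------
# BM/OU regime models

@dataclass
class ModelFit:
    model: str
    loglik: float
    params: dict
    k: int
    n: int
    aicc: float
    hessian_ok: bool
    theta_ok: bool
    converged: bool
    states: list[str] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return self.hessian_ok and self.theta_ok and self.converged


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample-corrected Akaike information criterion."""
    if n - k - 1 <= 0:
        return np.inf
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


class _PaintedDesign:
    """Precomputed geometry of a painted tree for repeated likelihood evals."""

    def __init__(self, painted: RegimePaintedTree):
        self.painted = painted
        tree = painted.tree
        self.tree = tree
        self.M = tree.mrca_matrix()
        self.h = tree.node_height
        self.h_mrca = self.h[self.M]
        self.tip_h = self.h[: tree.n_tips]
        self.S = painted.regime_time_to_node()      # (n_nodes, k)
        self.S_mrca = self.S[self.M]                # (n, n, k)
        self.S_tip = self.S[: tree.n_tips]
        self.root_state = painted.root_state
        self.n_states = painted.n_states
        # per-edge segments flattened for OU recursions
        self.order = tree.postorder[::-1]

    # BM covariances -------------------------------------------------------
    def cov_bm1(self, sigma2: float) -> np.ndarray:
        C = sigma2 * self.h_mrca
        np.fill_diagonal(C, sigma2 * self.tip_h)
        return C

    def cov_bms(self, sigma2: np.ndarray) -> np.ndarray:
        C = self.S_mrca @ sigma2
        np.fill_diagonal(C, self.S_tip @ sigma2)
        return C

    # OU regime-weight matrix: E[x_tips] = W(a) @ θ  (mean is linear in θ)
    def ou_weights(self, a: float) -> np.ndarray:
        tree = self.tree
        k = self.n_states
        Wn = np.zeros((tree.n_nodes, k))
        Wn[tree.root, self.root_state] = 1.0
        for v in self.order:
            if v == tree.root:
                continue
            w = Wn[tree.parent[v]].copy()
            for st, dt in self.painted.segments[v]:
                d = np.exp(-a * dt)
                w *= d
                w[st] += 1.0 - d
            Wn[v] = w
        return Wn[: tree.n_tips]

    # OU tip covariance for unit overall scale (σ² = rho per regime)
    def ou_variance(self, a: float, rho: np.ndarray) -> np.ndarray:
        tree = self.tree
        V = np.zeros(tree.n_nodes)
        for v in self.order:
            if v == tree.root:
                continue
            var = V[tree.parent[v]]
            for st, dt in self.painted.segments[v]:
                d2 = np.exp(-2.0 * a * dt)
                var = var * d2 + rho[st] * (1.0 - d2) / (2.0 * a)
            V[v] = var
        expo = -(self.tip_h[:, None] + self.tip_h[None, :]
                 - 2.0 * self.h_mrca)
        C = np.exp(a * expo) * V[self.M]
        np.fill_diagonal(C, V[: tree.n_tips])
        return C

    # OU mean / covariance by exact per-segment recursion ------------------
    def ou_moments(self, a: float, sigma2: np.ndarray, theta: np.ndarray):
        tree = self.tree
        E = np.empty(tree.n_nodes)
        V = np.empty(tree.n_nodes)
        E[tree.root] = theta[self.root_state]
        V[tree.root] = 0.0
        for v in self.order:
            if v == tree.root:
                continue
            e, var = E[tree.parent[v]], V[tree.parent[v]]
            for st, dt in self.painted.segments[v]:
                d = np.exp(-a * dt)
                e = theta[st] + (e - theta[st]) * d
                var = var * d * d + sigma2[st] * (1.0 - d * d) / (2.0 * a)
            E[v], V[v] = e, var
        mean = E[: tree.n_tips]
        expo = -(self.tip_h[:, None] + self.tip_h[None, :] - 2.0 * self.h_mrca)
        C = np.exp(a * expo) * V[self.M]
        np.fill_diagonal(C, V[: tree.n_tips])
        return mean, C


def _model_param_spec(model: str, k: int):
    """(names, per-regime flags) of free parameters in fitting order."""
    if model == "BM1":
        return ["root", "log_sigma2"]
    if model == "BMS":
        return ["root"] + [f"log_sigma2_{r}" for r in range(k)]
    if model == "OU1":
        return ["log_alpha", "log_sigma2", "theta"]
    if model == "OUM":
        return ["log_alpha", "log_sigma2"] + [f"theta_{r}" for r in range(k)]
    if model == "OUMV":
        return ["log_alpha"] + [f"log_sigma2_{r}" for r in range(k)] + \
            [f"theta_{r}" for r in range(k)]
    raise ValueError(f"unknown model {model!r}")


def fit_trait_model(painted: RegimePaintedTree, trait, model: str,
                    n_starts: int = 5, seed: int = 0) -> ModelFit:
    """ML fit of one BM/OU regime model on a painted tree.

    Multi-start quasi-Newton optimization on log-parameterized rates; the
    numerical Hessian at the optimum must be positive definite
    (``hessian_ok``) and optima must fall within an order of magnitude of
    the observed trait range (``theta_ok``) for the fit to count as valid.
    """
    x = _align_trait(painted.tree, trait)
    design = _PaintedDesign(painted)
    k = design.n_states
    if model in ("BMS", "OUM", "OUMV"):
        present = set(design.painted.observed_states())
        if len(present) < k:
            missing = sorted(set(range(k)) - present)
            raise ValueError(f"regimes {missing} absent from the painting")
    names = _model_param_spec(model, k)
    npar = len(names)
    rng = np.random.default_rng(seed)

    def unpack(p: np.ndarray):
        d = dict(zip(names, p))
        if model == "BM1":
            return d["root"], np.exp(d["log_sigma2"])
        if model == "BMS":
            return d["root"], np.exp([d[f"log_sigma2_{r}"] for r in range(k)])
        a = np.exp(d["log_alpha"])
        if model == "OU1":
            s2 = np.full(k, np.exp(d["log_sigma2"]))
            th = np.full(k, d["theta"])
        elif model == "OUM":
            s2 = np.full(k, np.exp(d["log_sigma2"]))
            th = np.array([d[f"theta_{r}"] for r in range(k)])
        else:
            s2 = np.exp([d[f"log_sigma2_{r}"] for r in range(k)])
            th = np.array([d[f"theta_{r}"] for r in range(k)])
        return a, s2, th

    def nll(p: np.ndarray) -> float:
        try:
            if model == "BM1":
                root, s2 = unpack(p)
                ll = _mvn_loglik(x, np.full(x.size, root),
                                 design.cov_bm1(s2))
            elif model == "BMS":
                root, s2 = unpack(p)
                ll = _mvn_loglik(x, np.full(x.size, root),
                                 design.cov_bms(s2))
            else:
                a, s2, th = unpack(p)
                mean, C = design.ou_moments(a, s2, th)
                ll = _mvn_loglik(x, mean, C)
        except (np.linalg.LinAlgError, FloatingPointError):
            return 1e10
        return 1e10 if not np.isfinite(ll) else -ll

    # The optimum-location parameters and the overall rate scale enter the
    # Gaussian likelihood linearly/as a scale, so they are profiled out by
    # GLS: the numerical search runs only over the OU pull a and (for
    # multi-rate models) the σ² ratios between regimes.  The validity
    # Hessian is still taken in the full statistical parameterization.
    n = x.size

    def profiled(red: np.ndarray):
        try:
            if model == "BM1":
                C0, W = design.cov_bm1(1.0), np.ones((n, 1))
                a_val, rho = None, np.ones(k)
            elif model == "BMS":
                rho = np.concatenate([[1.0], np.exp(red)])
                C0, W = design.cov_bms(rho), np.ones((n, 1))
                a_val = None
            else:
                a_val = np.exp(red[0])
                rho = np.ones(k) if model != "OUMV" else \
                    np.concatenate([[1.0], np.exp(red[1:])])
                C0 = design.ou_variance(a_val, rho)
                W = np.ones((n, 1)) if model == "OU1" else \
                    design.ou_weights(a_val)
            c = cho_factor(C0, check_finite=False)
            Ci_W = cho_solve(c, W, check_finite=False)
            A = W.T @ Ci_W
            b = W.T @ cho_solve(c, x, check_finite=False)
            try:
                theta = np.linalg.solve(A, b)
            except np.linalg.LinAlgError:
                theta = np.linalg.lstsq(A, b, rcond=None)[0]
            r = x - W @ theta
            rss = float(r @ cho_solve(c, r, check_finite=False))
            s_hat = max(rss / n, 1e-300)
            logdet = 2.0 * np.log(np.diag(c[0])).sum()
            lnl = -0.5 * (n * np.log(2 * np.pi * s_hat) + logdet + n)
        except (np.linalg.LinAlgError, FloatingPointError, ValueError):
            return -np.inf, None
        if not np.isfinite(lnl):
            return -np.inf, None
        return lnl, (a_val, s_hat * rho, theta)

    red_dim = {"BM1": 0, "BMS": k - 1, "OU1": 1, "OUM": 1,
               "OUMV": k}[model]
    if red_dim == 0:
        lnl_best, full_best = profiled(np.zeros(0))
        success = full_best is not None
    else:
        bounds_red = []
        if model in ("OU1", "OUM", "OUMV"):
            bounds_red.append((np.log(1e-8), np.log(ALPHA_MAX)))
        bounds_red += [(-14.0, 14.0)] * (red_dim - len(bounds_red))
        a_starts = np.log([0.1, 0.5, 2.0, 8.0, 32.0])
        lnl_best, full_best, success = -np.inf, None, False
        for s in range(n_starts):
            r0 = []
            if model in ("OU1", "OUM", "OUMV"):
                r0.append(a_starts[s % a_starts.size]
                          + (rng.normal(0, 0.3) if s >= a_starts.size
                             else 0.0))
            while len(r0) < red_dim:
                r0.append(rng.normal(0, 1.0) if s else 0.0)
            res = optimize.minimize(
                lambda p: -profiled(p)[0], np.array(r0),
                method="L-BFGS-B", bounds=bounds_red)
            if -res.fun > lnl_best:
                lnl_best, full_best = profiled(res.x)
                success = bool(res.success)
    if full_best is None:
        raise FloatingPointError(f"{model} likelihood degenerate")
    a_hat, sig2_hat, theta_hat = full_best
    loglik = float(lnl_best)

    # assemble the full parameter vector for the validity Hessian
    p_full = []
    for nm in names:
        if nm == "log_alpha":
            p_full.append(np.log(a_hat))
        elif nm == "log_sigma2":
            p_full.append(np.log(max(sig2_hat[0], 1e-300)))
        elif nm.startswith("log_sigma2_"):
            r_i = int(nm.rsplit("_", 1)[1])
            p_full.append(np.log(max(sig2_hat[r_i], 1e-300)))
        elif nm in ("root", "theta"):
            p_full.append(float(theta_hat[0]))
        else:                                   # theta_r
            r_i = int(nm.rsplit("_", 1)[1])
            p_full.append(float(theta_hat[min(r_i, theta_hat.size - 1)]))
    hess_ok = _hessian_pd(nll, np.array(p_full))

    if model in ("BM1", "BMS"):
        raw = {"root": float(theta_hat[0]),
               "sigma2": np.atleast_1d(sig2_hat).astype(float)}
        optima = np.array([theta_hat[0]])
    else:
        optima = np.full(k, theta_hat[0]) if model == "OU1" else \
            np.asarray(theta_hat, dtype=float)
        raw = {"alpha": float(a_hat),
               "sigma2": np.atleast_1d(sig2_hat).astype(float),
               "theta": optima}
    # order-of-magnitude sanity on the raw (10^trait) scale
    theta_ok = bool(np.all(optima >= x.min() - 1.0) and
                    np.all(optima <= x.max() + 1.0))
    return ModelFit(model=model, loglik=loglik, params=raw, k=npar,
                    n=n, aicc=aicc(loglik, npar, n),
                    hessian_ok=hess_ok, theta_ok=theta_ok,
                    converged=success,
                    states=list(design.painted.states))


def _hessian_pd(f, x0: np.ndarray, eps: float = 1e-4) -> bool:
    n = x0.size
    H = np.empty((n, n))
    f0 = f(x0)
    steps = eps * np.maximum(1.0, np.abs(x0))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = steps[i]
            ej = np.zeros(n); ej[j] = steps[j]
            H[i, j] = H[j, i] = (
                f(x0 + ei + ej) - f(x0 + ei - ej)
                - f(x0 - ei + ej) + f(x0 - ei - ej)
            ) / (4 * steps[i] * steps[j])
    try:
        ev = np.linalg.eigvalsh((H + H.T) / 2)
    except np.linalg.LinAlgError:
        return False
    return bool(np.all(ev > 0))


# ---------------------------------------------------------------------------
# model selection

@dataclass
class ModelSelectionTable:
    table: pd.DataFrame                 # model, n_valid, mean AICc, Δ, weight
    best_tally: dict[str, int]          # per-map best-model counts
    frac_second_within_2: float

    def __str__(self) -> str:
        return self.table.to_string(index=False)


def model_select(fits_per_map: list[dict[str, ModelFit]],
                 models: tuple[str, ...] = ("BM1", "BMS", "OU1", "OUM",
                                            "OUMV")) -> ModelSelectionTable:
    """AICc model comparison across stochastic maps.

    Invalid fits (bad Hessian, out-of-range optima, failed convergence) are
    discarded before averaging.  Akaike weights are computed from the mean
    AICc per model: w_i = exp(−Δ_i/2) / Σ_j exp(−Δ_j/2).
    """
    if not fits_per_map:
        raise ValueError("no fits supplied")
    mean_aicc: dict[str, float] = {}
    n_valid: dict[str, int] = {}
    for m in models:
        vals = [fm[m].aicc for fm in fits_per_map
                if m in fm and fm[m].valid and np.isfinite(fm[m].aicc)]
        n_valid[m] = len(vals)
        mean_aicc[m] = float(np.mean(vals)) if vals else np.nan
    return summarize_aicc(mean_aicc, n_valid, fits_per_map, models)


def summarize_aicc(mean_aicc: dict[str, float], n_valid: dict[str, int],
                   fits_per_map: list[dict[str, ModelFit]] | None,
                   models: tuple[str, ...]) -> ModelSelectionTable:
    avail = [m for m in models if np.isfinite(mean_aicc.get(m, np.nan))]
    if not avail:
        raise ValueError("all models invalid on every map")
    best = min(mean_aicc[m] for m in avail)
    delta = {m: mean_aicc[m] - best for m in avail}
    w_raw = {m: np.exp(-delta[m] / 2.0) for m in avail}
    tot = sum(w_raw.values())
    weight = {m: w_raw[m] / tot for m in avail}
    rows = []
    for m in models:
        rows.append({
            "model": m,
            "n_valid": n_valid.get(m, 0),
            "mean_aicc": mean_aicc.get(m, np.nan),
            "delta_aicc": delta.get(m, np.nan),
            "weight": weight.get(m, 0.0 if m not in avail else np.nan),
        })
    tally: dict[str, int] = {m: 0 for m in models}
    frac2 = np.nan
    if fits_per_map:
        n_with2 = 0
        n_maps = 0
        for fm in fits_per_map:
            valid = {m: fm[m].aicc for m in fm
                     if fm[m].valid and np.isfinite(fm[m].aicc)}
            if not valid:
                continue
            n_maps += 1
            bm = min(valid, key=valid.get)
            tally[bm] += 1
            others = [v for m, v in valid.items() if m != bm]
            if others and min(others) - valid[bm] <= 2.0:
                n_with2 += 1
        frac2 = n_with2 / n_maps if n_maps else np.nan
    return ModelSelectionTable(pd.DataFrame(rows), tally, float(frac2))


def akaike_weights(aicc_values: dict[str, float]) -> dict[str, float]:
    """Akaike weights from a set of AICc values (smaller AICc = better)."""
    best = min(aicc_values.values())
    w = {m: np.exp(-(v - best) / 2.0) for m, v in aicc_values.items()}
    tot = sum(w.values())
    return {m: v / tot for m, v in w.items()}
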
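"""Simulators for comparative datasets with known generating parameters.

Pure-birth (Yule) trees rescaled to unit root height, continuous-time Markov
regime histories painted along branches, continuous traits evolved under
single- or multi-regime Brownian motion and Ornstein–Uhlenbeck processes
(exact Gaussian transition densities per branch segment), and regression /
coevolution datasets with a known slope, Pagel's λ and bivariate Brownian
correlation.  Traits are generated directly on the log10 scale on which the
comparative analyses operate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trees import Phylogeny, RegimePaintedTree

__all__ = [
    "simulate_yule_tree", "simulate_discrete_history", "simulate_trait",
    "simulate_regression_dataset", "simulate_bivariate_bm",
    "TRAIT_MODELS",
]

TRAIT_MODELS = ("BM1", "BMS", "OU1", "OUM", "OUMV")


def simulate_yule_tree(n_tips: int, birth_rate: float = 1.0,
                       seed: int | None = None) -> Phylogeny:
    """Pure-birth tree with ``n_tips`` tips, rescaled to unit root height.

    Lineages split at rate ``birth_rate`` each; after the n-th tip appears
    the tree is extended by the waiting time to the (unobserved) next split,
    then all root-to-tip depths are scaled to 1.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = np.random.default_rng(seed)
    # active lineages: (node_id, birth_time)
    parent = [-1]
    birth_time = [0.0]
    active = [0]
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        i = active[rng.integers(k)]
        for _ in range(2):
            parent.append(i)
            birth_time.append(t)
            active.append(len(parent) - 1)
        active.remove(i)
    t += rng.exponential(1.0 / (birth_rate * n_tips))
    end_time = {v: t for v in active}
    n_nodes = len(parent)
    elen = np.zeros(n_nodes)
    for v in range(n_nodes):
        if parent[v] >= 0:
            tv = end_time.get(v, None)
            if tv is None:
                # internal node: ends when it splits (= birth of children)
                tv = min(birth_time[c] for c in range(n_nodes)
                         if parent[c] == v)
            elen[v] = tv - birth_time[v]
    # reindex tips-first
    tips = sorted(active)
    internal = [v for v in range(n_nodes) if v not in end_time]
    order = {v: i for i, v in enumerate(tips)}
    order.update({v: len(tips) + j for j, v in enumerate(internal)})
    new_parent = np.full(n_nodes, -1, dtype=int)
    new_elen = np.zeros(n_nodes)
    for v in range(n_nodes):
        new_parent[order[v]] = order[parent[v]] if parent[v] >= 0 else -1
        new_elen[order[v]] = elen[v]
    labels = [f"t{i+1}" for i in range(n_tips)]
    tree = Phylogeny(new_parent, new_elen, labels)
    return tree.rescale(1.0)


def simulate_discrete_history(tree: Phylogeny, Q: np.ndarray,
                              root_freqs: np.ndarray | None = None,
                              seed: int | None = None) -> RegimePaintedTree:
    """Regime history under a continuous-time Markov model along the tree.

    Exponential waiting times between state changes on each branch, starting
    from a root state drawn from ``root_freqs`` (uniform by default).
    """
    Q = np.asarray(Q, dtype=float)
    k = Q.shape[0]
    if Q.shape != (k, k) or np.any(Q - np.diag(np.diag(Q)) < 0) or \
            np.max(np.abs(Q.sum(axis=1))) > 1e-10 * max(1.0, np.abs(Q).max()):
        raise ValueError("malformed rate matrix: rows must sum to 0 with "
                         "non-negative off-diagonals")
    rng = np.random.default_rng(seed)
    if root_freqs is None:
        root_freqs = np.full(k, 1.0 / k)
    root_state = int(rng.choice(k, p=np.asarray(root_freqs) /
                                np.sum(root_freqs)))
    node_state = np.empty(tree.n_nodes, dtype=int)
    node_state[tree.root] = root_state
    segments: list[list[tuple[int, float]]] = [[] for _ in range(tree.n_nodes)]
    for v in tree.postorder[::-1]:          # preorder: parents first
        if v == tree.root:
            continue
        s = node_state[tree.parent[v]]
        remaining = tree.edge_length[v]
        segs: list[tuple[int, float]] = []
        while True:
            rate = -Q[s, s]
            wait = rng.exponential(1.0 / rate) if rate > 0 else np.inf
            if wait >= remaining:
                segs.append((s, float(remaining)))
                break
            segs.append((s, float(wait)))
            remaining -= wait
            probs = Q[s].copy()
            probs[s] = 0.0
            probs /= probs.sum()
            s = int(rng.choice(k, p=probs))
        node_state[v] = s
        segments[v] = segs
    return RegimePaintedTree(tree, segments, root_state,
                             [str(i) for i in range(k)])


def _segment_step(x: float, state: int, dt: float, model: str, params: dict,
                  rng: np.random.Generator) -> float:
    """Exact transition over one constant-regime segment."""
    if dt == 0:
        return x
    if model in ("BM1", "BMS"):
        sig2 = params["sigma2"][state] if model == "BMS" else params["sigma2"]
        return x + rng.normal(0.0, np.sqrt(sig2 * dt)) if sig2 > 0 else x
    a = params["alpha"]
    theta = params["theta"][state] if model in ("OUM", "OUMV") \
        else params["theta"]
    sig2 = params["sigma2"][state] if model == "OUMV" else params["sigma2"]
    e = np.exp(-a * dt)
    mean = theta + (x - theta) * e
    var = sig2 * (1.0 - e * e) / (2.0 * a)
    return mean + (rng.normal(0.0, np.sqrt(var)) if var > 0 else 0.0)


def simulate_trait(painted: RegimePaintedTree, model: str, params: dict,
                   seed: int | None = None) -> pd.Series:
    """Continuous trait along a painted tree under BM/OU regime models.

    ``params`` must supply ``root`` (ancestral value) plus, per model:
    BM1 ``sigma2`` scalar; BMS ``sigma2`` per-regime array; OU1 ``alpha``,
    ``sigma2``, ``theta`` scalars; OUM adds per-regime ``theta``; OUMV
    per-regime ``theta`` and ``sigma2``.  Transitions are exact (Gaussian)
    per branch segment, so no Euler discretization error.
    """
    if model not in TRAIT_MODELS:
        raise ValueError(f"unknown model {model!r}")
    _check_params(model, params, painted.n_states)
    rng = np.random.default_rng(seed)
    tree = painted.tree
    x = np.empty(tree.n_nodes)
    x[tree.root] = params["root"]
    for v in tree.postorder[::-1]:
        if v == tree.root:
            continue
        val = x[tree.parent[v]]
        for state, dur in painted.segments[v]:
            val = _segment_step(val, state, dur, model, params, rng)
        x[v] = val
    return pd.Series(x[: tree.n_tips], index=tree.tip_labels, name="trait")


def _check_params(model: str, params: dict, k: int) -> None:
    need = {"BM1": ["root", "sigma2"], "BMS": ["root", "sigma2"],
            "OU1": ["root", "alpha", "sigma2", "theta"],
            "OUM": ["root", "alpha", "sigma2", "theta"],
            "OUMV": ["root", "alpha", "sigma2", "theta"]}[model]
    for key in need:
        if key not in params:
            raise ValueError(f"model {model} requires parameter {key!r}")
    for key, per_regime in (("sigma2", model in ("BMS", "OUMV")),
                            ("theta", model in ("OUM", "OUMV"))):
        if key in params and per_regime and np.ndim(params[key]) == 0:
            raise ValueError(f"model {model} needs per-regime {key!r}")
        if per_regime and len(np.atleast_1d(params[key])) != k:
            raise ValueError(f"{key!r} must have one entry per regime ({k})")
    if "alpha" in need and params["alpha"] <= 0:
        raise ValueError("OU pull alpha must be positive")


def lambda_cov(tree: Phylogeny, lam: float) -> np.ndarray:
    """Phylogenetic covariance with off-diagonals scaled by Pagel's λ."""
    C = tree.vcv()
    d = np.diag(C).copy()
    C = lam * C
    np.fill_diagonal(C, d)
    return C


def simulate_regression_dataset(tree: Phylogeny, slopes, intercept: float,
                                lam: float, sigma2: float,
                                bivariate_correlation: float | None = None,
                                seed: int | None = None) -> pd.DataFrame:
    """Response = intercept + Xβ + MVN(0, σ²·C(λ)) with BM predictors.

    Predictors are independent unit-rate Brownian traits; the error follows
    the λ-scaled phylogenetic covariance.  When ``bivariate_correlation`` is
    given, two extra columns ``u``/``v`` carry a correlated bivariate
    Brownian pair with that evolutionary correlation.
    """
    slopes = np.atleast_1d(np.asarray(slopes, dtype=float))
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    if bivariate_correlation is not None and \
            not abs(bivariate_correlation) < 1:
        raise ValueError("|bivariate correlation| must be < 1")
    rng = np.random.default_rng(seed)
    n = tree.n_tips
    C = tree.vcv()
    L = np.linalg.cholesky(C + 1e-12 * np.eye(n))
    X = L @ rng.standard_normal((n, slopes.size))
    Clam = lambda_cov(tree, lam)
    Llam = np.linalg.cholesky(Clam + 1e-12 * np.eye(n))
    y = intercept + X @ slopes + np.sqrt(sigma2) * (
        Llam @ rng.standard_normal(n))
    df = pd.DataFrame(X, index=tree.tip_labels,
                      columns=[f"x{i+1}" for i in range(slopes.size)])
    df.insert(0, "y", y)
    if bivariate_correlation is not None:
        uv = simulate_bivariate_bm(tree, bivariate_correlation,
                                   seed=rng.integers(2 ** 31))
        df["u"], df["v"] = uv["u"], uv["v"]
    return df


def simulate_bivariate_bm(tree: Phylogeny, correlation: float,
                          sigma2: tuple[float, float] = (1.0, 1.0),
                          means: tuple[float, float] = (0.0, 0.0),
                          seed: int | None = None) -> pd.DataFrame:
    """Two traits under correlated Brownian motion (Kronecker covariance)."""
    if not abs(correlation) < 1:
        raise ValueError("|correlation| must be < 1")
    rng = np.random.default_rng(seed)
    n = tree.n_tips
    C = tree.vcv()
    L = np.linalg.cholesky(C + 1e-12 * np.eye(n))
    R = np.array([[sigma2[0], correlation * np.sqrt(sigma2[0] * sigma2[1])],
                  [correlation * np.sqrt(sigma2[0] * sigma2[1]), sigma2[1]]])
    Lr = np.linalg.cholesky(R)
    Z = L @ rng.standard_normal((n, 2)) @ Lr.T
    return pd.DataFrame({"u": means[0] + Z[:, 0], "v": means[1] + Z[:, 1]},
                        index=tree.tip_labels)
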
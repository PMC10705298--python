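"""Mk-model ancestral-state reconstruction of the power category.

A continuous-time Markov chain over the states {MD, CD, FD} evolves along
the tree; rates are fitted by maximum likelihood with Felsenstein's pruning
algorithm, and per-node marginal ("scaled") likelihoods are obtained by the
re-rooting construction: at each internal node the likelihood of the data
below the node (pruning partials) is combined with the likelihood of the
rest of the tree given the node state, then normalized to sum to one.

Model structures: equal-rates (ER, default), symmetric (SYM), and
all-rates-different (ARD).  Root prior: flat over states (default) or the
stationary distribution of the fitted rate matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize, minimize_scalar

__all__ = [
    "MkFit",
    "NodeStateLikelihoods",
    "fit_mk",
    "marginal_node_likelihoods",
    "mk_log_likelihood",
]

STRUCTURES = ("ER", "SYM", "ARD")


@dataclass
class MkFit:
    """Fitted Mk model: state set, rate matrix Q (rows sum to 0), lnL."""

    states: tuple
    Q: np.ndarray
    lnL: float
    structure: str
    root_prior: str = "flat"
    converged: bool = True
    degenerate: bool = False

    def __post_init__(self):
        rows = np.abs(self.Q.sum(axis=1))
        if np.any(rows > 1e-10):
            raise ValueError("Q rows must sum to 0")

    @property
    def k(self) -> int:
        return len(self.states)

    def prior(self) -> np.ndarray:
        if self.root_prior == "flat":
            return np.full(self.k, 1.0 / self.k)
        if self.root_prior == "stationary":
            return _stationary(self.Q)
        raise ValueError(f"unknown root prior {self.root_prior!r}")


@dataclass
class NodeStateLikelihoods:
    """Per-internal-node scaled likelihood vectors (each sums to one)."""

    states: tuple
    node_probs: dict = field(repr=False)  # node index -> vector

    def probability(self, node: int, state: str) -> float:
        return float(self.node_probs[node][self.states.index(state)])

    def as_rows(self) -> list:
        return [
            {"node": n, **{s: float(v[i]) for i, s in enumerate(self.states)}}
            for n, v in sorted(self.node_probs.items())
        ]


def _stationary(Q: np.ndarray) -> np.ndarray:
    k = Q.shape[0]
    A = np.vstack([Q.T, np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    return np.clip(pi, 0.0, None) / np.clip(pi, 0.0, None).sum()


def _build_Q(structure: str, rates: np.ndarray, k: int) -> np.ndarray:
    Q = np.zeros((k, k))
    if structure == "ER":
        Q[:] = rates[0]
    elif structure == "SYM":
        iu = np.triu_indices(k, 1)
        Q[iu] = rates
        Q[(iu[1], iu[0])] = rates
    elif structure == "ARD":
        idx = 0
        for i in range(k):
            for j in range(k):
                if i != j:
                    Q[i, j] = rates[idx]
                    idx += 1
    else:
        raise ValueError(f"unknown structure {structure!r}; expected one of {STRUCTURES}")
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _n_rates(structure: str, k: int) -> int:
    return {"ER": 1, "SYM": k * (k - 1) // 2, "ARD": k * (k - 1)}[structure]


def _tip_partials(tree, states_by_tip, state_set) -> np.ndarray:
    k = len(state_set)
    L = np.zeros((tree.n_nodes, k))
    for i in tree.tip_indices():
        s = states_by_tip[tree.label[i]]
        L[i, state_set.index(s)] = 1.0
    return L


def _pruning(tree, L_tips, Q, prior):
    """Postorder pruning.  Returns (lnL, down partials D, log scalers).

    D[v] is the (rescaled) likelihood of the data below v given the state
    at v; per-node log scale factors are accumulated separately.
    """
    n = tree.n_nodes
    k = Q.shape[0]
    D = L_tips.copy()
    logscale = np.zeros(n)
    P = {}
    for i in range(1, n):
        P[i] = expm(Q * tree.blen[i])
    tipset = set(tree.tip_indices().tolist())
    for v in range(n - 1, -1, -1):
        if v in tipset:
            continue
        vec = np.ones(k)
        ls = 0.0
        for c in tree.children(v):
            vec = vec * (P[c] @ D[c])
            ls += logscale[c]
        m = vec.max()
        if not np.isfinite(m) or m <= 0:
            return -np.inf, D, logscale
        D[v] = vec / m
        logscale[v] = ls + np.log(m)
    root = 0
    lik = float(prior @ D[root])
    if lik <= 0:
        return -np.inf, D, logscale
    return np.log(lik) + logscale[root], D, logscale


def mk_log_likelihood(tree, states_by_tip, Q, state_set, prior=None) -> float:
    """Pruning-algorithm log-likelihood of tip states under rate matrix Q."""
    state_set = tuple(state_set)
    if prior is None:
        prior = np.full(len(state_set), 1.0 / len(state_set))
    L = _tip_partials(tree, states_by_tip, state_set)
    lnL, _, _ = _pruning(tree, L, Q, prior)
    return float(lnL)


def fit_mk(tree, states, structure: str = "ER", root_prior: str = "flat",
           state_set=None) -> MkFit:
    """ML fit of the Mk model to tip states.

    ``states`` maps tip label -> state (or is a sequence aligned with
    ``tree.tip_labels``).  With a single observed state the fit is
    degenerate: rate 0 with a warning.
    """
    if not isinstance(states, dict):
        states = dict(zip(tree.tip_labels, states))
    missing = set(tree.tip_labels) - set(states)
    if missing:
        raise ValueError(f"tips without a state: {sorted(missing)}")
    observed = sorted({states[t] for t in tree.tip_labels})
    if state_set is None:
        state_set = tuple(observed)
    else:
        state_set = tuple(state_set)
        if not set(observed) <= set(state_set):
            raise ValueError("observed states outside the declared state set")
    k = len(state_set)
    if len(observed) < 2:
        warnings.warn("single observed state: degenerate Mk fit with rate 0",
                      stacklevel=2)
        Q = np.zeros((k, k))
        prior = np.full(k, 1.0 / k)
        return MkFit(state_set, Q, float(np.log(prior[0])), structure,
                     root_prior, converged=True, degenerate=True)

    L = _tip_partials(tree, states, state_set)
    prior = np.full(k, 1.0 / k)
    nr = _n_rates(structure, k)
    T = tree.height()

    max_rate = 1e4 / max(T, 1e-9)

    def nll(logr):
        rates = np.exp(np.asarray(logr, dtype=float))
        if np.any(~np.isfinite(rates)) or np.any(rates > max_rate):
            return 1e10  # keep the simplex away from expm overflow
        Q = _build_Q(structure, rates, k)
        lnL, _, _ = _pruning(tree, L, Q, prior)
        return -lnL if np.isfinite(lnL) else 1e10

    x0 = np.full(nr, np.log(1.0 / max(T, 1e-9)))
    if nr == 1:
        res = minimize_scalar(lambda r: nll(np.array([r])),
                              bounds=(np.log(1e-8 / max(T, 1e-9)),
                                      np.log(1e4 / max(T, 1e-9))),
                              method="bounded", options={"xatol": 1e-10})
        rates = np.exp([res.x])
        ok = res.success
        lnL = -res.fun
    else:
        res = minimize(nll, x0, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
        rates = np.exp(res.x)
        ok = res.success
        lnL = -res.fun
    if not ok or not np.isfinite(lnL):
        raise RuntimeError(f"Mk fit did not converge (structure={structure})")
    Q = _build_Q(structure, rates, k)
    fit = MkFit(state_set, Q, float(lnL), structure, root_prior, converged=True)
    return fit


def marginal_node_likelihoods(fit: MkFit, tree, states) -> NodeStateLikelihoods:
    """Marginal (re-rooted) scaled likelihoods at every internal node.

    Each vector is the posterior probability of the node being in each
    state given all tip data under the fitted model, normalized to sum to
    one.
    """
    if not isinstance(states, dict):
        states = dict(zip(tree.tip_labels, states))
    k = fit.k
    prior = fit.prior()
    tipset = set(tree.tip_indices().tolist())
    if fit.degenerate:
        obs = {states[t] for t in tree.tip_labels}
        vec = np.zeros(k)
        vec[fit.states.index(next(iter(obs)))] = 1.0
        probs = {v: vec.copy() for v in range(tree.n_nodes) if v not in tipset}
        return NodeStateLikelihoods(fit.states, probs)

    L = _tip_partials(tree, states, fit.states)
    _, D, _ = _pruning(tree, L, fit.Q, prior)
    P = {i: expm(fit.Q * tree.blen[i]) for i in range(1, tree.n_nodes)}

    # "up" partial G[v]: likelihood of all data outside v's subtree, as a
    # function of v's state, carrying the root prior; computed in preorder.
    G = np.zeros((tree.n_nodes, k))
    G[0] = prior
    for v in range(tree.n_nodes):
        if v in tipset:
            continue
        kids = tree.children(v)
        msgs = {c: P[c] @ D[c] for c in kids}
        for c in kids:
            if c in tipset:
                continue
            sib = np.ones(k)
            for s in kids:
                if s != c:
                    sib = sib * msgs[s]
            G[c] = P[c].T @ (G[v] * sib)
            m = G[c].max()
            if m > 0:
                G[c] = G[c] / m
    probs = {}
    for v in range(tree.n_nodes):
        if v in tipset:
            continue
        w = D[v] * G[v]
        probs[v] = w / w.sum()
    return NodeStateLikelihoods(fit.states, probs)
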
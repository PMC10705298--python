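"""Continuous-trait ancestral states with evolutionary-model selection.

Traits (log10 scale) are modelled as multivariate normal with covariance
sigma^2 * V(theta), where V is the phylogenetic VCV under one of six
models: Brownian motion (BM) and five one-parameter extensions (Pagel's
lambda, kappa, delta, Ornstein-Uhlenbeck, early-burst).  Each model is
fitted by ML with the mean (root state) and rate profiled analytically and
the shape parameter optimized numerically; models that beat BM by a
likelihood-ratio test (p < 0.05) compete on AIC, and the winner's
parameters rescale the tree before reconstruction.

Ancestral states are the BM conditional means given the tips: the trait
values over the whole tree form a Gaussian Markov random field whose
precision is the branch-length-weighted graph Laplacian (edge weight
1/branch length), so with a flat root prior the internal-node conditional
mean solves a sparse harmonic system and the conditional covariance is the
inverse internal-block Laplacian times sigma^2.  These equal the classical
generalized-least-squares ancestral estimates.  95% CIs use the normal
quantile 1.959964; estimates are back-transformed by 10**x for ratio-scale
reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from .treeio import PhyloTree, transform_branch_lengths, vcv_matrix

__all__ = [
    "EvolutionModelFit",
    "NodeEstimates",
    "fit_evolution_models",
    "select_and_rescale",
    "reconstruct_continuous",
    "bm_profile_loglik",
]

Z95 = 1.959964
MODELS = ("BM", "lambda", "kappa", "delta", "OU", "EB")
#: search bounds for each shape parameter (OU/EB rates are per My)
SHAPE_BOUNDS = {
    "lambda": (0.0, 1.0),
    "kappa": (1e-6, 3.0),
    "delta": (1e-5, 3.0),
    "OU": (0.0, 10.0),
    "EB": (-5.0, 0.0),
}


@dataclass
class EvolutionModelFit:
    model: str
    sigma2: float
    root: float
    shape: float | None  # lambda, kappa, delta, OU alpha, or EB rate; None for BM
    lnL: float
    k: int  # parameter count

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.lnL

    lrt_p: float | None = None  # vs BM; None for BM itself


@dataclass
class NodeEstimates:
    """Per-internal-node MLE and 95% CI on the log10 analysis scale, with
    ratio-scale back-transforms."""

    node_mle: dict = field(repr=False)   # node index -> log10-scale MLE
    node_ci: dict = field(repr=False)    # node index -> (lo, hi), log10 scale
    sigma2: float = float("nan")

    def ratio_mle(self, node: int) -> float:
        return float(10.0 ** self.node_mle[node])

    def ratio_ci(self, node: int) -> tuple:
        lo, hi = self.node_ci[node]
        return (float(10.0 ** lo), float(10.0 ** hi))

    def nodes(self) -> list:
        return sorted(self.node_mle)


def bm_profile_loglik(V: np.ndarray, x: np.ndarray) -> tuple:
    """Profile ML of x ~ N(mu 1, sigma^2 V): returns (lnL, mu_hat, s2_hat)."""
    n = len(x)
    sign, logdet = np.linalg.slogdet(V)
    if sign <= 0:
        return -np.inf, np.nan, np.nan
    Vi = np.linalg.solve(V, np.column_stack([x, np.ones(n)]))
    Vix, Vi1 = Vi[:, 0], Vi[:, 1]
    mu = float(x @ Vi1) / float(np.ones(n) @ Vi1) if float(np.ones(n) @ Vi1) != 0 else np.nan
    r = x - mu
    s2 = float(r @ (Vix - mu * Vi1)) / n
    if not np.isfinite(s2) or s2 <= 0:
        s2 = max(s2, 1e-12)
    lnL = -0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)
    return float(lnL), mu, float(s2)


def fit_evolution_models(tree: PhyloTree, trait, models=MODELS) -> list:
    """Fit BM and the one-parameter extensions by ML.

    ``trait`` is a mapping tip label -> log10 value or a sequence aligned
    with ``tree.tip_labels``.  Models that fail (non-finite likelihood or a
    singular covariance) are excluded from the returned list; BM failing is
    an error.  Each non-BM fit carries a likelihood-ratio p-value vs BM.
    """
    if isinstance(trait, dict):
        x = np.array([trait[t] for t in tree.tip_labels], dtype=float)
    else:
        x = np.asarray(trait, dtype=float)
    if len(x) != tree.n_tips:
        raise ValueError("trait length does not match tip count")
    if tree.n_tips < 4:
        raise ValueError("need at least 4 tips with trait values")
    labels, V0 = vcv_matrix(tree)

    lnL_bm, mu, s2 = bm_profile_loglik(V0, x)
    if not np.isfinite(lnL_bm):
        raise RuntimeError("Brownian-motion fit failed: singular covariance")
    fits = [EvolutionModelFit("BM", s2, mu, None, lnL_bm, k=2)]

    for model in models:
        if model == "BM":
            continue
        lo, hi = SHAPE_BOUNDS[model]

        BAD = 1e10  # finite penalty keeps the bounded optimizer happy

        def nll(theta, _model=model):
            try:
                _, Vt = transform_branch_lengths((labels, V0), _model, theta)
                lnL, _, _ = bm_profile_loglik(Vt, x)
            except Exception:
                return BAD
            return -lnL if np.isfinite(lnL) else BAD

        res = minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-8})
        if not np.isfinite(res.fun) or res.fun >= BAD:
            continue  # excluded: did not converge
        theta = float(res.x)
        _, Vt = transform_branch_lengths((labels, V0), model, theta)
        lnL, mu_m, s2_m = bm_profile_loglik(Vt, x)
        stat = max(0.0, 2.0 * (lnL - lnL_bm))
        fits.append(EvolutionModelFit(
            model, s2_m, mu_m, theta, float(lnL), k=3,
            lrt_p=float(chi2.sf(stat, df=1)),
        ))
    return fits


def select_and_rescale(fits, tree: PhyloTree, alpha: float = 0.05) -> PhyloTree:
    """Rescale the tree by the best-AIC model among those that beat BM.

    Only models with a significant likelihood-ratio test vs BM (p < alpha)
    compete; if none do, the tree is returned untransformed.
    """
    if not fits:
        raise ValueError("no fitted models")
    winners = [f for f in fits if f.model != "BM" and f.lrt_p is not None
               and f.lrt_p < alpha]
    if not winners:
        return tree.copy()
    best = min(winners, key=lambda f: f.aic)
    return transform_branch_lengths(tree, best.model, best.shape)


def reconstruct_continuous(tree: PhyloTree, trait) -> NodeEstimates:
    """ML ancestral states with 95% CIs for a complete tip trait.

    Solves the harmonic system of the branch-length-weighted graph
    Laplacian (flat root prior); equivalent to dense GLS conditional means.
    """
    if isinstance(trait, dict):
        x = np.array([trait[t] for t in tree.tip_labels], dtype=float)
    else:
        x = np.asarray(trait, dtype=float)
    if len(x) != tree.n_tips:
        raise ValueError("trait length does not match tip count")
    if tree.height() <= 0:
        raise ValueError("zero-depth tree")

    n = tree.n_nodes
    tips = tree.tip_indices()
    tipset = set(tips.tolist())
    internal = [v for v in range(n) if v not in tipset]
    # weighted Laplacian over all nodes, edge weight 1 / branch length
    L = np.zeros((n, n))
    for i in range(1, n):
        w = 1.0 / max(tree.blen[i], 1e-10)
        p = tree.parent[i]
        L[i, i] += w
        L[p, p] += w
        L[i, p] -= w
        L[p, i] -= w
    A = L[np.ix_(internal, internal)]
    B = L[np.ix_(internal, tips)]
    mean = np.linalg.solve(A, -B @ x)

    # ML rate from the BM profile likelihood on the same tree
    _, V = vcv_matrix(tree)
    _, _, s2 = bm_profile_loglik(V, x)
    s2 = max(s2, 1e-12)  # zero-variance degenerate input keeps CIs defined
    var = s2 * np.diag(np.linalg.inv(A))

    node_mle = {v: float(m) for v, m in zip(internal, mean)}
    node_ci = {
        v: (float(m - Z95 * np.sqrt(s)), float(m + Z95 * np.sqrt(s)))
        for v, m, s in zip(internal, mean, var)
    }
    return NodeEstimates(node_mle, node_ci, sigma2=float(s2))
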
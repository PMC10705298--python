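"""Phylogenetic logistic regression with parametric bootstrap inference.

The binary power label (male-biased power = 1) is regressed on one
standardized predictor under a logistic mean model while the residual
correlation among species follows the phylogeny.  The estimator is a
quasi-likelihood / GEE scheme in the spirit of the binary-trait
phylogenetic regression of Ives & Garland:

* mean model      P(y_i = 1) = logistic(b0 + b1 x_i)
* working correlation  R(lambda) = (1 - lambda) I + lambda * corr(V)

where V is the phylogenetic variance-covariance matrix and
lambda in [0, 1] is the phylogenetic-signal parameter, estimated by a
method-of-moments fit of standardized-residual cross-products to the
working correlation.  On a star phylogeny corr(V) = I, so the estimating
equations reduce exactly to ordinary logistic-regression IRLS.

Inference uses a parametric bootstrap: the binary trait is re-simulated up
the tree under the fitted model (a two-state switching process whose
stationary probability at each tip is the fitted logistic mean), the model
is refit to each replicate, and percentile confidence intervals and
two-sided p-values are read off the replicate distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar
from scipy.special import expit

__all__ = [
    "LogisticFit",
    "BootstrapSummary",
    "SeparationError",
    "ConvergenceError",
    "fit_phylogistic",
    "parametric_bootstrap",
    "significance_stars",
]

#: convergence tolerance on the estimating-equation score norm
SCORE_TOL = 1e-8
MAX_ITER = 300
#: outer iterations alternating coefficient and signal updates
MAX_OUTER = 40
#: ridge keeping the estimating equations coercive under near-singular
#: working correlation (shifts well-conditioned solutions by ~1e-5)
RIDGE = 1e-4
#: trust-region cap on the Newton step length
MAX_STEP = 2.0


class SeparationError(RuntimeError):
    """The two classes are (quasi-)separated; logistic MLE does not exist."""


class ConvergenceError(RuntimeError):
    """Estimating equations failed to converge."""


@dataclass
class LogisticFit:
    """Result of a single phylogenetic logistic regression.

    Coding convention: male-biased power (MP) = 1, so positive ``b1``
    increases the probability of male-biased power.
    """

    b0: float
    b1: float
    se_b0: float
    se_b1: float
    signal: float  # phylogenetic signal lambda in [0, 1]
    converged: bool
    n: int
    n_iter: int
    coding: str = "MP=1 (positive b1 favors male-biased power)"
    criterion_path: list = field(default_factory=list)

    @property
    def t0(self) -> float:
        return self.b0 / self.se_b0

    @property
    def t1(self) -> float:
        return self.b1 / self.se_b1

    def linear_predictor(self, x) -> np.ndarray:
        return self.b0 + self.b1 * np.asarray(x, dtype=float)

    def to_dict(self) -> dict:
        return {
            "b0": self.b0, "b1": self.b1,
            "se_b0": self.se_b0, "se_b1": self.se_b1,
            "t0": self.t0, "t1": self.t1,
            "signal": self.signal, "converged": self.converged,
            "n": self.n, "coding": self.coding,
        }


@dataclass
class BootstrapSummary:
    """Parametric-bootstrap summary of a :class:`LogisticFit`.

    ``ci_*`` are percentile intervals of the replicate distribution;
    ``basic_ci_*`` reflect the bootstrap bias/skew back around the point
    estimate (the "basic" interval), which is the inferential interval
    because the point estimator is biased upward under strong phylogenetic
    signal — the reason the bootstrap is run for parameter estimation in
    the first place.  ``bias_corrected_*`` = 2 * point estimate - replicate
    mean removes the first-order bias.
    """

    reps: int
    alpha: float
    seed: int
    point_b0: float
    point_b1: float
    mean_b0: float
    mean_b1: float
    ci_b0: tuple
    ci_b1: tuple
    p_b0: float
    p_b1: float
    n_failed: int
    replicates_b0: np.ndarray = field(repr=False)
    replicates_b1: np.ndarray = field(repr=False)

    @property
    def bias_corrected_b0(self) -> float:
        return 2.0 * self.point_b0 - self.mean_b0

    @property
    def bias_corrected_b1(self) -> float:
        return 2.0 * self.point_b1 - self.mean_b1

    @property
    def basic_ci_b0(self) -> tuple:
        return (2 * self.point_b0 - self.ci_b0[1], 2 * self.point_b0 - self.ci_b0[0])

    @property
    def basic_ci_b1(self) -> tuple:
        return (2 * self.point_b1 - self.ci_b1[1], 2 * self.point_b1 - self.ci_b1[0])

    def to_dict(self) -> dict:
        return {
            "reps": self.reps, "alpha": self.alpha, "seed": self.seed,
            "point_b0": self.point_b0, "point_b1": self.point_b1,
            "mean_b0": self.mean_b0, "mean_b1": self.mean_b1,
            "ci_b0": list(self.ci_b0), "ci_b1": list(self.ci_b1),
            "basic_ci_b0": list(self.basic_ci_b0),
            "basic_ci_b1": list(self.basic_ci_b1),
            "bias_corrected_b0": self.bias_corrected_b0,
            "bias_corrected_b1": self.bias_corrected_b1,
            "p_b0": self.p_b0, "p_b1": self.p_b1, "n_failed": self.n_failed,
        }


def significance_stars(p: float) -> str:
    """Report-table stars: *** p<0.001, ** p<0.01, * p<0.05."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _correlation(V: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(V))
    rho = V / np.outer(d, d)
    np.fill_diagonal(rho, 1.0)
    return rho


def _factor_R(rho: np.ndarray, lam: float):
    n = rho.shape[0]
    R = (1.0 - lam) * np.eye(n) + lam * rho
    try:
        return cho_factor(R, lower=True)
    except np.linalg.LinAlgError:
        return cho_factor(R + 1e-10 * np.eye(n), lower=True)


def _solve_b(X, y, R_factor, b_start, deviance_criterion):
    """Fisher scoring for the GEE coefficients at a fixed signal value.

    ``R_factor`` is the Cholesky factorization of the working correlation;
    the working covariance is R scaled by the binomial variances, so each
    iteration costs one triangular solve.

    With an identity working correlation this is classical IRLS and
    step-halving enforces a monotone binomial deviance.  With phylogenetic
    correlation the scheme is a damped Newton iteration on the estimating
    equations: a tiny ridge (RIDGE) keeps the equations coercive when the
    working correlation is nearly singular, and steps are capped in length;
    the recorded criterion (score norm) is monitored for divergence.
    """
    b = b_start.copy()
    path = []

    n = len(y)
    rhs = np.empty((n, 3))
    ridge = 0.0 if deviance_criterion else RIDGE

    def pieces(bv):
        eta = X @ bv
        if np.max(np.abs(eta)) > 30.0:
            raise SeparationError(
                "linear predictor diverged; classes appear separated"
            )
        mu = expit(eta)
        a = mu * (1.0 - mu)
        sa = np.sqrt(a)
        rhs[:, 0] = sa
        rhs[:, 1] = sa * X[:, 1]
        rhs[:, 2] = (y - mu) / sa
        Ri = cho_solve(R_factor, rhs, check_finite=False)
        W = rhs[:, :2]
        info = W.T @ Ri[:, :2] + ridge * np.eye(2)
        U = W.T @ Ri[:, 2] - ridge * bv
        if deviance_criterion:
            crit = -2.0 * float(np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu)))
        else:
            crit = float(np.sqrt(U @ U))
        return mu, U, info, crit

    mu, U, info, crit = pieces(b)
    path.append(crit)
    it = 0
    if deviance_criterion:
        for it in range(1, MAX_ITER + 1):
            if np.linalg.norm(U) < SCORE_TOL:
                break
            step = np.linalg.solve(info, U)
            # step halving on the monotone deviance
            for _ in range(30):
                cand = b + step
                try:
                    mu2, U2, info2, crit2 = pieces(cand)
                except SeparationError:
                    step *= 0.5
                    continue
                if crit2 <= crit + 1e-12 or np.linalg.norm(U2) < SCORE_TOL:
                    b, mu, U, info, crit = cand, mu2, U2, info2, crit2
                    break
                step *= 0.5
            else:
                break
            path.append(crit)
    else:
        best = crit
        stall = 0
        for it in range(1, MAX_ITER + 1):
            if crit < SCORE_TOL:
                break
            step = np.linalg.solve(info, U)
            norm = float(np.sqrt(step @ step))
            if norm > MAX_STEP:
                step *= MAX_STEP / norm
            try:
                mu, U, info, crit = pieces(b + step)
            except SeparationError:
                step *= 0.25
                mu, U, info, crit = pieces(b + step)
            b = b + step
            path.append(crit)
            if crit < best - 1e-12:
                best = crit
                stall = 0
            else:
                stall += 1
                if stall > 60:
                    break
    converged = bool(np.linalg.norm(U) < max(SCORE_TOL, 1e-6))
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    return b, se, mu, converged, it, path


def _estimate_signal(y, mu, rho) -> float:
    """Moment estimator of the signal parameter.

    Weighted regression of standardized-residual cross-products on the
    Brownian correlation, weights rho_ij: closely related pairs carry the
    information about phylogenetic clustering, while the many distant
    low-correlation pairs mostly add noise.
    """
    e = (y - mu) / np.sqrt(np.clip(mu * (1.0 - mu), 1e-12, None))
    iu = np.triu_indices(len(y), k=1)
    w = rho[iu]
    num = float(np.sum(w * e[iu[0]] * e[iu[1]] * rho[iu]))
    den = float(np.sum(w * rho[iu] ** 2))
    if den <= 0:
        return 0.0
    return float(np.clip(num / den, 0.0, 1.0))


def fit_phylogistic(y, x, C, signal=None) -> LogisticFit:
    """Fit the phylogenetic logistic regression.

    Parameters
    ----------
    y : array of 0/1 labels (1 = male-biased power)
    x : standardized predictor, same order as ``y``
    C : phylogenetic covariance — either the matrix itself or a
        ``(labels, V)`` pair from :func:`phylopower.treeio.vcv_matrix`
    signal : fix the signal parameter instead of estimating it (optional)
    """
    if isinstance(C, tuple):
        C = C[1]
    V = np.asarray(C, dtype=float)
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = len(y)
    if not (len(x) == n == V.shape[0] == V.shape[1]):
        raise ValueError("y, x and covariance matrix sizes disagree")
    if n < 10:
        raise ValueError(f"need at least 10 species, got {n}")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("y must be coded 0/1")
    if len(np.unique(y)) < 2:
        raise SeparationError("y has a single class; model is degenerate")

    rho = _correlation(V)
    X = np.column_stack([np.ones(n), x])
    b = np.zeros(2)
    lam = 0.0 if signal is None else float(signal)
    if not 0.0 <= lam <= 1.0:
        raise ValueError("signal must be in [0, 1]")
    path_all = []
    total_iter = 0
    converged = False
    # the estimating equations can lose their root when the working
    # correlation is too strong for the data; lam_cap tracks the largest
    # signal level at which they remain solvable
    lam_cap = 1.0 if signal is None else lam

    def attempt(lam_try, b_try):
        fac = _factor_R(rho, lam_try)
        return _solve_b(X, y, fac, b_try, lam_try == 0.0)

    for _ in range(MAX_OUTER if signal is None else 1):
        try:
            b2, se, mu, converged, it, path = attempt(lam, b)
        except SeparationError:
            if lam == 0.0 or signal is not None:
                raise
            lam_cap = lam * 0.5
            lam = lam_cap
            continue
        path_all.extend(path)
        total_iter += it
        if not converged:
            if lam == 0.0 or signal is not None:
                break
            lam_cap = lam * 0.5
            lam = lam_cap
            continue
        b = b2
        if signal is not None:
            break
        new_lam = min(_estimate_signal(y, mu, rho), lam_cap)
        if abs(new_lam - lam) < 1e-3:
            break
        # damped update: the moment estimator can oscillate on small samples
        lam = min(0.5 * lam + 0.5 * new_lam, lam_cap)
    # final solve at the settled signal value
    b, se, mu, converged, it, path = attempt(lam, b)
    path_all.extend(path)
    total_iter += it
    if not converged:
        raise ConvergenceError(
            f"estimating equations did not converge after {total_iter} iterations "
            f"(signal={lam:.3f})"
        )
    return LogisticFit(
        b0=float(b[0]), b1=float(b[1]),
        se_b0=float(se[0]), se_b1=float(se[1]),
        signal=float(lam), converged=converged, n=n, n_iter=total_iter,
        criterion_path=path_all,
    )


def _signal_to_retention(fit, tree, x, rho):
    """State-retention parameter g for the bootstrap simulator.

    Chosen so the label correlation the simulator actually induces (its
    implied correlation, computed exactly) matches the fitted working
    correlation lambda * corr(V), in rho-weighted least squares.
    """
    from .synthetic_data import implied_label_correlation

    if fit.signal <= 0.0:
        return 0.0
    iu = np.triu_indices(rho.shape[0], k=1)
    target = fit.signal * rho[iu]
    w = rho[iu]

    def loss(g):
        C = implied_label_correlation(tree, x, fit.b0, fit.b1, g)
        return float(np.sum(w * (C[iu] - target) ** 2))

    res = minimize_scalar(loss, bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": 1e-3})
    return float(res.x)


def parametric_bootstrap(
    fit: LogisticFit, tree, x, reps: int = 2000, alpha: float = 0.05,
    seed: int = 0, max_fail_frac: float = 0.2,
) -> BootstrapSummary:
    """Parametric bootstrap of a converged fit.

    Each replicate simulates the binary trait up the tree under the fitted
    model (stationary tip probabilities at the fitted logistic mean, state
    retention matched to the fitted signal), refits, and records the
    coefficient estimates.  Percentile CIs at level ``alpha`` and two-sided
    percentile p-values are reported.  Aborts if more than
    ``max_fail_frac`` of replicates fail to converge.
    """
    from .synthetic_data import simulate_binary_power
    from .treeio import vcv_matrix

    if not fit.converged:
        raise ValueError("refusing to bootstrap a non-converged fit")
    x = np.asarray(x, dtype=float)
    labels, V = vcv_matrix(tree)
    if len(labels) != len(x):
        raise ValueError("predictor length does not match tree tips")
    rho = _correlation(V)
    g = _signal_to_retention(fit, tree, x, rho)
    rng_root = np.random.SeedSequence(seed)
    child_seeds = rng_root.generate_state(reps)

    b0s, b1s = [], []
    n_failed = 0
    for r in range(reps):
        ystar = simulate_binary_power(
            tree, x, fit.b0, fit.b1, signal=g, seed=int(child_seeds[r] % (2**31)),
        )
        try:
            refit = fit_phylogistic(ystar, x, V)
        except (SeparationError, ConvergenceError):
            n_failed += 1
            if n_failed > max_fail_frac * reps:
                raise RuntimeError(
                    f"bootstrap aborted: {n_failed}/{r + 1} replicates failed "
                    f"to converge (limit {max_fail_frac:.0%})"
                )
            continue
        b0s.append(refit.b0)
        b1s.append(refit.b1)
    b0s = np.array(b0s)
    b1s = np.array(b1s)

    def pct_ci(v):
        lo, hi = np.quantile(v, [alpha / 2, 1 - alpha / 2])
        return (float(lo), float(hi))

    def pct_p(v):
        # two-sided percentile p-value: does the replicate distribution
        # straddle zero?
        lo = float(np.mean(v <= 0.0))
        hi = float(np.mean(v >= 0.0))
        return float(min(1.0, 2.0 * min(lo, hi)))

    return BootstrapSummary(
        reps=reps, alpha=alpha, seed=seed,
        point_b0=fit.b0, point_b1=fit.b1,
        mean_b0=float(b0s.mean()), mean_b1=float(b1s.mean()),
        ci_b0=pct_ci(b0s), ci_b1=pct_ci(b1s),
        p_b0=pct_p(b0s), p_b1=pct_p(b1s),
        n_failed=n_failed,
        replicates_b0=b0s, replicates_b1=b1s,
    )
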
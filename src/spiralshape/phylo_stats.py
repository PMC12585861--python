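"""Phylogenetic signal and phylogenetic regression.

Blomberg's K compares the observed ratio of among-species variance to
phylogenetically corrected variance against its Brownian-motion
expectation; K = 1 under Brownian motion on the given tree, K < 1 when
relatives resemble each other less than expected, K > 1 when more. Kmult is
its multivariate extension (sums of squares accumulated over trait
columns). Significance comes from permuting trait values across tips.

PGLS fits a linear model whose error covariance follows the tree, with
Pagel's lambda (scaling of the off-diagonal shared history) estimated by
maximum likelihood. The multivariate shape regression uses the
weighted-average-lambda procedure: lambda is fitted per shape principal
component, averaged with weights given by each component's share of shape
variance, and the resulting single lambda transforms the tree for a
multivariate fit whose significance comes from residual randomization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import minimize_scalar

from .io_formats import Phylogeny
from .shape_core import ProcrustesSample

__all__ = [
    "PhyloCovariance",
    "SignalResult",
    "PGLSFit",
    "phylo_cov",
    "blomberg_k",
    "k_mult",
    "pgls",
    "interaction_pgls",
    "weighted_lambda_pgls",
    "fdr_adjust",
]


@dataclass
class PhyloCovariance:
    C: np.ndarray  # (n, n)
    tip_labels: list[str]


@dataclass
class SignalResult:
    statistic: str  # "K" | "Kmult"
    value: float
    p_value: float
    n_perm: int
    seed: int | None


@dataclass
class PGLSFit:
    coefficients: np.ndarray
    std_errors: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    lambda_: float
    r_squared: float
    log_likelihood: float
    n: int
    residuals: np.ndarray
    fitted: np.ndarray
    f_statistic: float | None = None
    f_p_value: float | None = None


# ---------------------------------------------------------------------------
# covariance from the tree
# ---------------------------------------------------------------------------

def phylo_cov(tree: Phylogeny) -> np.ndarray:
    """Brownian-motion covariance: C_ij = depth of the MRCA of tips i, j.

    Valid for non-ultrametric trees (fossil tips): the diagonal holds each
    tip's own root-to-tip depth. Tip order follows ``tree.tip_labels``.
    """
    n = tree.tip_count
    tip_pos = {int(t): i for i, t in enumerate(tree.tip_indices)}
    C = np.zeros((n, n))
    for node in range(1, tree.n_nodes):
        mask = np.zeros(n, dtype=bool)
        for t in tree.subtree_nodes(node):
            if t in tip_pos:
                mask[tip_pos[t]] = True
        C[np.ix_(mask, mask)] += tree.length[node]
    return C


def _align(y: np.ndarray, labels, tree: Phylogeny) -> np.ndarray:
    if labels is None:
        return np.asarray(y, dtype=float)
    labels = list(labels)
    if sorted(labels) != sorted(tree.tip_labels):
        missing = set(tree.tip_labels) ^ set(labels)
        raise ValueError(f"species do not match tree tips: {sorted(missing)}")
    order = [labels.index(t) for t in tree.tip_labels]
    return np.asarray(y, dtype=float)[order]


# ---------------------------------------------------------------------------
# phylogenetic signal
# ---------------------------------------------------------------------------

def _k_statistic(Y: np.ndarray, C: np.ndarray, Cinv: np.ndarray) -> float:
    """Shared machinery of K and Kmult (Y is n x d)."""
    n = Y.shape[0]
    ones = np.ones(n)
    denom = ones @ Cinv @ ones
    a = (ones @ Cinv @ Y) / denom
    R = Y - a
    mse0 = float(np.sum(R * R))  # ordinary sum of squared deviations
    mse = float(np.sum(R * (Cinv @ R)))  # phylogenetically corrected
    if mse0 == 0.0 or mse == 0.0:
        raise ValueError("constant trait data; K undefined")
    expected = (np.trace(C) - n / denom) / (n - 1)
    return (mse0 / mse) / expected


def blomberg_k(
    y: np.ndarray,
    tree: Phylogeny,
    labels=None,
    n_perm: int = 999,
    seed: int | None = None,
) -> SignalResult:
    """Blomberg's K for one trait, with a tip-permutation p-value."""
    y = _align(np.asarray(y, float).ravel(), labels, tree)
    return _signal(y[:, None], tree, "K", n_perm, seed)


def k_mult(
    Y: np.ndarray | ProcrustesSample,
    tree: Phylogeny,
    labels=None,
    n_perm: int = 999,
    seed: int | None = None,
) -> SignalResult:
    """Multivariate phylogenetic signal (Kmult) for a trait matrix."""
    if isinstance(Y, ProcrustesSample):
        labels = [c.species_id for c in Y.configurations]
        Y = Y.coordinate_matrix()
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    Y = _align(Y, labels, tree)
    return _signal(Y, tree, "Kmult", n_perm, seed)


def _signal(Y, tree, name, n_perm, seed) -> SignalResult:
    n = Y.shape[0]
    if n < 4:
        raise ValueError("phylogenetic signal needs at least 4 species")
    C = phylo_cov(tree)
    Cinv = np.linalg.inv(C)
    obs = _k_statistic(Y, C, Cinv)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _k_statistic(Y[perm], C, Cinv) >= obs:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return SignalResult(name, float(obs), float(p), n_perm, seed)


# ---------------------------------------------------------------------------
# PGLS
# ---------------------------------------------------------------------------

def _lambda_cov(C: np.ndarray, lam: float) -> np.ndarray:
    Cl = C * lam
    np.fill_diagonal(Cl, np.diag(C))
    return Cl


def _gls_profile(y: np.ndarray, X: np.ndarray, C: np.ndarray, lam: float):
    """GLS fit at fixed lambda; ML sigma^2 (divisor n) and profile logL."""
    n = len(y)
    Cl = _lambda_cov(C, lam)
    L = np.linalg.cholesky(Cl)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    yw = np.linalg.solve(L, y)
    Xw = np.linalg.solve(L, X)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid_w = yw - Xw @ beta
    rss = float(resid_w @ resid_w)
    sigma2 = rss / n
    if sigma2 <= 0:
        sigma2 = np.finfo(float).tiny
    logL = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)
    return beta, rss, sigma2, logL, Cl, Xw, yw


def pgls(
    y: np.ndarray,
    X: np.ndarray,
    tree: Phylogeny,
    labels=None,
    lam: float | None = None,
) -> PGLSFit:
    """Phylogenetic GLS with ML Pagel's lambda (or a fixed ``lam``).

    ``X`` must include the intercept column. R^2 is computed from GLS sums
    of squares about the GLS mean. Wald t tests per coefficient use the
    ML sigma^2 rescaled to the unbiased (n - p) denominator.
    """
    y = _align(np.asarray(y, float).ravel(), labels, tree)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if labels is not None:
        order = [list(labels).index(t) for t in tree.tip_labels]
        X = X[order]
    n, p = X.shape
    if n != len(y):
        raise ValueError("y and X row counts differ")
    if n <= p:
        raise ValueError("need more species than predictors")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank-deficient")
    C = phylo_cov(tree)

    if lam is None:
        res = minimize_scalar(
            lambda L: -_gls_profile(y, X, C, L)[3],
            bounds=(0.0, 1.0), method="bounded",
            options={"xatol": 1e-8},
        )
        lam_hat = float(res.x)
        # the bounded search can miss a boundary optimum by its tolerance
        cands = [lam_hat, 0.0, 1.0]
        lam_hat = max(cands, key=lambda L: _gls_profile(y, X, C, L)[3])
    else:
        lam_hat = float(lam)

    beta, rss, sigma2, logL, Cl, Xw, yw = _gls_profile(y, X, C, lam_hat)
    dof = n - p
    s2 = rss / dof
    XtX_inv = np.linalg.inv(Xw.T @ Xw)
    se = np.sqrt(np.clip(np.diag(XtX_inv) * s2, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)

    # GLS total sum of squares about the GLS mean
    tss = _gls_profile(y, np.ones((n, 1)), C, lam_hat)[1]
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    r2 = float(np.clip(r2, 0.0, 1.0))

    q = p - 1
    f_stat = f_p = None
    if q > 0 and rss > 0:
        f_stat = float(((tss - rss) / q) / (rss / dof))
        f_p = float(stats.f.sf(f_stat, q, dof))
    elif q > 0:
        f_stat, f_p = np.inf, 0.0

    fitted = X @ beta
    return PGLSFit(
        coefficients=beta,
        std_errors=se,
        t_values=tvals,
        p_values=pvals,
        lambda_=lam_hat,
        r_squared=r2,
        log_likelihood=float(logL),
        n=n,
        residuals=y - fitted,
        fitted=fitted,
        f_statistic=f_stat,
        f_p_value=f_p,
    )


def interaction_pgls(
    turns: np.ndarray,
    mass: np.ndarray,
    length: np.ndarray,
    tree: Phylogeny,
    labels=None,
) -> PGLSFit:
    """PGLS of turn count on mass, length and their interaction.

    Design: [1, mass, length, mass * length]. The fitted values support
    observed-versus-expected coiling plots; the interaction coefficient
    tests whether the effect of cochlear length on coiling depends on
    body size.
    """
    mass = np.asarray(mass, dtype=float).ravel()
    length = np.asarray(length, dtype=float).ravel()
    X = np.column_stack([np.ones(len(mass)), mass, length, mass * length])
    return pgls(np.asarray(turns, float).ravel(), X, tree, labels=labels)


def weighted_lambda_pgls(
    sample: ProcrustesSample | np.ndarray,
    X: np.ndarray,
    tree: Phylogeny,
    labels=None,
    n_perm: int = 999,
    seed: int | None = None,
) -> dict:
    """Multivariate shape regression with a weighted-average lambda.

    Pagel's lambda is estimated by ML for the regression of every shape
    principal component (all with nonzero variance) on ``X``; the weighted
    average (weights = per-component share of shape variance) transforms
    the tree, the shape data and design are whitened by the transformed
    covariance, and the multivariate R^2 is tested by residual
    randomization.
    """
    from .ordination import pca  # deferred: ordination imports this module

    if isinstance(sample, ProcrustesSample):
        labels = [c.species_id for c in sample.configurations]
        Y = sample.coordinate_matrix()
    else:
        Y = np.asarray(sample, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    Y = _align(Y, labels, tree)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if labels is not None:
        order = [list(labels).index(t) for t in tree.tip_labels]
        X = X[order]
    n = Y.shape[0]

    ord_ = pca(Y)
    keep = ord_.eigenvalues > 1e-12 * max(float(ord_.eigenvalues[0]), 1e-300)
    scores = ord_.scores[:, keep]
    weights = ord_.eigenvalues[keep]
    weights = weights / weights.sum()

    lams = np.array([
        pgls(scores[:, j], X, tree).lambda_ for j in range(scores.shape[1])
    ])
    lam_bar = float(np.sum(weights * lams))

    C = phylo_cov(tree)
    Cl = _lambda_cov(C, lam_bar)
    L = np.linalg.cholesky(Cl)
    Yw = np.linalg.solve(L, Y)
    Xw = np.linalg.solve(L, X)
    onesw = np.linalg.solve(L, np.ones((n, 1)))

    def multiv_r2(Yw_: np.ndarray) -> float:
        beta0, *_ = np.linalg.lstsq(onesw, Yw_, rcond=None)
        R0 = Yw_ - onesw @ beta0
        beta, *_ = np.linalg.lstsq(Xw, Yw_, rcond=None)
        R1 = Yw_ - Xw @ beta
        sst = float(np.sum(R0 * R0))
        sse = float(np.sum(R1 * R1))
        return 1.0 - sse / sst if sst > 0 else 1.0

    r2_obs = multiv_r2(Yw)
    # residual randomization about the reduced (intercept-only) model
    beta0, *_ = np.linalg.lstsq(onesw, Yw, rcond=None)
    fitted0 = onesw @ beta0
    resid0 = Yw - fitted0
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if multiv_r2(fitted0 + resid0[perm]) >= r2_obs:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return {
        "lambda_bar": lam_bar,
        "per_pc_lambda": lams,
        "weights": weights,
        "r_squared": float(np.clip(r2_obs, 0.0, 1.0)),
        "p_value": float(p),
        "n_perm": n_perm,
    }


def fdr_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out
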
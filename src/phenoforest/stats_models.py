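"""Differential-abundance models.

Per-phenotype testing uses a binomial generalized linear mixed model with
a logit link and a Gaussian random intercept per subject (equivalently an
observation-level overdispersion effect when each subject contributes one
sample):

    c_i ~ Binomial(n_i, mu_i),   logit(mu_i) = b0 + b1 Responder_i + xi_i

fitted by maximum likelihood with adaptive Gauss-Hermite quadrature and
tested by a Wald test on b1 (Bonferroni-adjusted across phenotypes by
default).  The multivariate PFDA model stacks all phenotypes matching a
partial annotation, with cluster main effects, cluster x responder
interactions, a responder main effect and an observation-level random
effect; differential abundance is the one-sided test of the positivity
of  b_R + mean_j(interaction_j),  a contrast invariant to the
reference-level parameterization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "GlmmFit",
    "DifferentialAbundanceResult",
    "PfdaResult",
    "fit_binomial_glmm",
    "differential_abundance",
    "pfda_test",
    "adjust_pvalues",
]

_GH_NODES = 25


@dataclass
class GlmmFit:
    beta: np.ndarray
    sigma: float
    se: np.ndarray
    loglik: float
    converged: bool
    method: str  # "glmm" or "betabinomial" (fallback)
    cov: np.ndarray | None = None


@dataclass
class DifferentialAbundanceResult:
    phenotype: str
    intercept: float
    effect: float  # responder coefficient on the logit scale
    sigma: float
    se: float
    p_value: float
    p_adjusted: float = np.nan
    method: str = "glmm"

    @property
    def direction(self) -> int:
        return int(np.sign(self.effect)) if np.isfinite(self.effect) else 0


@dataclass
class PfdaResult:
    contrast: float
    se: float
    p_value: float  # one-sided, H1: contrast > 0
    lower_95: float  # one-sided 95% confidence bound
    beta: np.ndarray
    sigma: float
    k: int
    converged: bool


def _glmm_negloglik(theta, X, c, n, groups, nodes, logw, ngroups):
    """Negative marginal log-likelihood by adaptive Gauss-Hermite
    quadrature.

    theta = (beta..., log sigma).  Each group's random-intercept integral
    is recentred at its posterior mode (Newton) and scaled by the local
    curvature, so the quadrature stays accurate for large binomial
    totals, whose integrands are extremely narrow.
    """
    p = X.shape[1]
    beta = theta[:p]
    sigma = np.exp(theta[p])
    eta = X @ beta
    u = np.zeros(ngroups)
    h = np.full(ngroups, -1.0)
    for _ in range(40):
        z = eta + sigma * u[groups]
        mu = expit(z)
        g1 = np.zeros(ngroups)
        np.add.at(g1, groups, c - n * mu)
        g1 = sigma * g1 - u
        w2 = np.zeros(ngroups)
        np.add.at(w2, groups, n * mu * (1.0 - mu))
        h = -sigma * sigma * w2 - 1.0
        step = np.clip(g1 / h, -4.0, 4.0)
        u = u - step
        if np.max(np.abs(step)) < 1e-11:
            break
    # curvature at the final mode
    z = eta + sigma * u[groups]
    mu = expit(z)
    w2 = np.zeros(ngroups)
    np.add.at(w2, groups, n * mu * (1.0 - mu))
    h = -sigma * sigma * w2 - 1.0
    tau = 1.0 / np.sqrt(-h)
    uu = u[:, None] + tau[:, None] * nodes[None, :]
    zz = eta[:, None] + sigma * uu[groups]
    # binomial log-kernel (theta-independent constants dropped)
    ll_obs = c[:, None] * zz - n[:, None] * np.logaddexp(0.0, zz)
    ll_g = np.zeros((ngroups, nodes.size))
    np.add.at(ll_g, groups, ll_obs)
    ll_g += -0.5 * uu**2 - 0.5 * np.log(2.0 * np.pi)
    contrib = logw[None, :] + 0.5 * nodes[None, :] ** 2 + ll_g
    m = contrib.max(axis=1)
    lg = np.log(np.sum(np.exp(contrib - m[:, None]), axis=1)) + m
    lg += np.log(tau)
    return -float(np.sum(lg))


def _fd_hessian(f, x, eps=1e-5):
    p = x.size
    h = np.empty((p, p))
    f0 = f(x)
    for i in range(p):
        for j in range(i, p):
            xi = x.copy(); xi[i] += eps; xi[j] += eps
            xj = x.copy(); xj[i] += eps
            xk = x.copy(); xk[j] += eps
            h[i, j] = h[j, i] = (f(xi) - f(xj) - f(xk) + f0) / eps**2
    return h


def _fit_glmm(X, c, n, groups):
    nodes, weights = hermegauss(_GH_NODES)
    logw = np.log(weights)
    groups = np.asarray(groups)
    ngroups = int(groups.max()) + 1
    # moment-based start
    p0 = np.clip((c.sum() + 0.5) / (n.sum() + 1.0), 1e-6, 1 - 1e-6)
    theta0 = np.zeros(X.shape[1] + 1)
    theta0[0] = np.log(p0 / (1 - p0))
    theta0[-1] = np.log(0.5)
    res = minimize(
        _glmm_negloglik, theta0,
        args=(X, c, n, groups, nodes, logw, ngroups),
        method="L-BFGS-B",
        bounds=[(None, None)] * X.shape[1] + [(-8.0, 3.0)],
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-7},
    )
    theta = res.x
    nllf = lambda t: _glmm_negloglik(
        t, X, c, n, groups, nodes, logw, ngroups
    )
    hess = _fd_hessian(nllf, theta)
    p = X.shape[1]
    try:
        cov_full = np.linalg.inv(hess)
        cov = cov_full[:p, :p]
        with np.errstate(invalid="ignore"):
            se = np.sqrt(np.diag(cov))
        ok = bool(res.success) and np.all(np.isfinite(se))
    except np.linalg.LinAlgError:
        cov = None
        se = np.full(p, np.nan)
        ok = False
    return GlmmFit(
        beta=theta[:p], sigma=float(np.exp(theta[p])), se=se,
        loglik=-float(res.fun), converged=ok, method="glmm", cov=cov,
    )


def _fit_betabinomial(X, c, n):
    """Fixed-effect beta-binomial fallback for non-convergent mixed fits."""
    from scipy.special import betaln

    def nll(theta):
        beta = theta[:-1]
        phi = np.exp(theta[-1])  # precision
        mu = expit(X @ beta)
        a = np.clip(mu * phi, 1e-8, None)
        b = np.clip((1 - mu) * phi, 1e-8, None)
        return -float(
            np.sum(betaln(c + a, n - c + b) - betaln(a, b))
        )

    theta0 = np.zeros(X.shape[1] + 1)
    p0 = np.clip((c.sum() + 0.5) / (n.sum() + 1.0), 1e-6, 1 - 1e-6)
    theta0[0] = np.log(p0 / (1 - p0))
    theta0[-1] = np.log(50.0)
    res = minimize(nll, theta0, method="Nelder-Mead",
                   options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
    hess = _fd_hessian(nll, res.x, eps=1e-4)
    p = X.shape[1]
    try:
        cov = np.linalg.inv(hess)[:p, :p]
        with np.errstate(invalid="ignore"):
            se = np.sqrt(np.diag(cov))
        ok = np.all(np.isfinite(se))
    except np.linalg.LinAlgError:
        cov, se, ok = None, np.full(p, np.nan), False
    return GlmmFit(beta=res.x[:p], sigma=np.nan, se=se,
                   loglik=-float(res.fun), converged=ok,
                   method="betabinomial", cov=cov)


def fit_binomial_glmm(counts, totals, responder, groups=None,
                      phenotype: str = "") -> DifferentialAbundanceResult:
    """Mixed-model differential abundance for one phenotype.

    ``groups`` defaults to one group per observation (a subject-level
    random effect when each subject contributes one sample).  On a failed
    mixed fit a beta-binomial fixed-effect model is used and flagged.
    """
    c = np.asarray(counts, dtype=float)
    n = np.asarray(totals, dtype=float)
    y = np.asarray(responder, dtype=float)
    if np.any(c > n) or np.any(c < 0):
        raise ValueError("need 0 <= counts <= totals")
    if len(set(y)) < 2:
        raise ValueError("both responder classes are required")
    X = np.column_stack([np.ones_like(y), y])
    if groups is None:
        groups = np.arange(c.size)
    fit = _fit_glmm(X, c, n, np.asarray(groups))
    if not fit.converged:
        fit = _fit_betabinomial(X, c, n)
    if fit.converged and fit.se[1] > 0:
        z = fit.beta[1] / fit.se[1]
        pval = float(2 * norm.sf(abs(z)))
    else:
        pval = np.nan
    return DifferentialAbundanceResult(
        phenotype=phenotype,
        intercept=float(fit.beta[0]),
        effect=float(fit.beta[1]),
        sigma=float(fit.sigma),
        se=float(fit.se[1]),
        p_value=pval,
        method=fit.method,
    )


def differential_abundance(count_matrix, responder,
                           method: str = "bonferroni") -> list:
    """Per-phenotype GLMM tests with multiplicity adjustment.

    ``count_matrix`` is a :class:`~phenoforest.phenotype_matrix.CountMatrix`
    (or any object with ``counts`` and ``totals``); ``responder`` maps its
    sample index to 0/1.
    """
    y = np.asarray(
        [responder[s] for s in count_matrix.counts.index], dtype=float
    )
    n = count_matrix.totals.loc[count_matrix.counts.index].to_numpy(float)
    results = []
    for p in count_matrix.counts.columns:
        c = count_matrix.counts[p].to_numpy(float)
        results.append(
            fit_binomial_glmm(c, n, y, phenotype=p)
        )
    raw = np.array([r.p_value for r in results])
    adj = adjust_pvalues(np.nan_to_num(raw, nan=1.0), method)
    for r, a in zip(results, adj):
        r.p_adjusted = float(a) if np.isfinite(r.p_value) else np.nan
    return results


def pfda_test(counts: pd.DataFrame, totals, responder) -> PfdaResult:
    """Joint differential-abundance test over matching phenotypes.

    ``counts`` holds one column per matching phenotype (k* >= 1) and one
    row per subject; the model stacks the N = n * k* observations with a
    reference-level parameterization and an observation-level random
    effect, and tests H1: b_R + mean_j(interaction_j) > 0 one-sided.
    """
    k = counts.shape[1]
    if k < 1:
        raise ValueError("no phenotypes match the target")
    subjects = counts.index
    nsub = len(subjects)
    tot = pd.Series(totals).loc[subjects].to_numpy(float)
    y = np.asarray([responder[s] for s in subjects], dtype=float)
    # stacked observations, cluster-major
    c = counts.to_numpy(float).T.reshape(-1)  # cluster j varies slowest
    n = np.tile(tot, k)
    resp = np.tile(y, k)
    cluster = np.repeat(np.arange(k), nsub)
    cols = [np.ones(nsub * k), resp]
    for j in range(1, k):
        cols.append((cluster == j).astype(float))
    for j in range(1, k):
        cols.append(((cluster == j) * resp))
    X = np.column_stack(cols)
    groups = np.arange(nsub * k)  # observation-level random effect
    fit = _fit_glmm(X, c, n, groups)
    # contrast: responder main effect + mean interaction (reference 0)
    L = np.zeros(X.shape[1])
    L[1] = 1.0
    if k > 1:
        L[1 + k : 1 + k + (k - 1)] = 1.0 / k
    est = float(L @ fit.beta)
    if fit.cov is not None:
        se = float(np.sqrt(L @ fit.cov @ L))
    else:
        se = np.nan
    if np.isfinite(se) and se > 0:
        pval = float(norm.sf(est / se))
        lower = est - norm.ppf(0.95) * se
    else:
        pval, lower = np.nan, np.nan
    return PfdaResult(
        contrast=est, se=se, p_value=pval, lower_95=float(lower),
        beta=fit.beta, sigma=fit.sigma, k=k, converged=fit.converged,
    )


def adjust_pvalues(pvalues, method: str = "bonferroni") -> np.ndarray:
    """Bonferroni or Benjamini-Hochberg adjustment (monotone, in [0,1])."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    if method in ("bh", "BH", "fdr_bh"):
        order = np.argsort(p)
        ranked = p[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(ranked, 1.0)
        return out
    raise ValueError(f"unknown adjustment method {method!r}")
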
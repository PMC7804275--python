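"""Random-intercept generalized linear mixed models via Gauss-Hermite quadrature.

Supports the families needed for the syllable edge-effect analyses: Gaussian
with identity or log link, inverse Gaussian with identity link, and binomial
with logit link, each with a single Gaussian random intercept per cluster
(individual). The marginal log-likelihood integrates the random effect with
adaptive-free Gauss-Hermite quadrature (the integrand is evaluated at
sqrt(2) * sigma_u * z_q around the fixed-effect predictor), and parameters are
estimated by maximum likelihood with L-BFGS. Likelihood-ratio tests between
nested fits are therefore internally consistent across families.

This is a compact, well-tested estimator for the narrow model class above, not
a general mixed-model framework; fits are cross-validated against R's
lme4/glmmTMB in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize
import scipy.special
import scipy.stats
from numpy.polynomial.hermite import hermgauss

__all__ = ["GLMMResult", "fit_glmm", "lrt"]

FAMILIES = {
    "gaussian_identity",
    "gaussian_log",
    "inverse_gaussian_identity",
    "binomial_logit",
}

_BIG = 1e10
_MU_EPS = 1e-9


@dataclass
class GLMMResult:
    family: str
    beta: np.ndarray
    sigma_u: float
    scale: float | None
    loglik: float
    converged: bool
    n_obs: int
    n_groups: int


def _log_density(y: np.ndarray, mu: np.ndarray, family: str, scale: float) -> np.ndarray:
    """Elementwise log density; mu is the linear predictor + random effect,
    already on the *link* scale for log/logit families."""
    if family == "gaussian_identity":
        return -0.5 * ((y - mu) / scale) ** 2 - np.log(scale) - 0.5 * np.log(2 * np.pi)
    if family == "gaussian_log":
        m = np.exp(np.clip(mu, -50, 50))
        return -0.5 * ((y - m) / scale) ** 2 - np.log(scale) - 0.5 * np.log(2 * np.pi)
    if family == "inverse_gaussian_identity":
        lam = scale
        m = np.maximum(mu, _MU_EPS)
        ll = 0.5 * (np.log(lam) - np.log(2 * np.pi) - 3 * np.log(y)) - lam * (y - m) ** 2 / (
            2 * m**2 * y
        )
        # identity link can push the mean negative; penalize smoothly
        return np.where(mu > _MU_EPS, ll, ll - 1e4 * (_MU_EPS - mu) ** 2)
    if family == "binomial_logit":
        # y in {0,1}; mu is the logit
        return y * mu - np.logaddexp(0.0, mu)
    raise ValueError(f"unknown family {family!r}")


def _unpack(theta: np.ndarray, p: int, family: str) -> tuple[np.ndarray, float, float]:
    beta = theta[:p]
    sigma_u = np.exp(np.clip(theta[p], -12, 6))
    scale = np.exp(np.clip(theta[p + 1], -12, 12)) if family != "binomial_logit" else 1.0
    return beta, float(sigma_u), float(scale)


def _neg_loglik(theta, y, X, starts, family, nodes, log_wts, p):
    # y, X are pre-sorted by cluster; `starts` are cluster start offsets
    beta, sigma_u, scale = _unpack(theta, p, family)
    eta = X @ beta
    # (n_obs, Q) linear predictors with the random effect at each node
    shift = np.sqrt(2.0) * sigma_u * nodes
    ll_obs = _log_density(y[:, None], eta[:, None] + shift[None, :], family, scale)
    if not np.all(np.isfinite(ll_obs)):
        ll_obs = np.nan_to_num(ll_obs, nan=-_BIG, posinf=-_BIG, neginf=-_BIG)
    # sum within clusters, then log-sum-exp over quadrature nodes
    grp = np.add.reduceat(ll_obs, starts, axis=0)
    ll = scipy.special.logsumexp(grp + log_wts[None, :], axis=1).sum()
    return -ll


def fit_glmm(
    y,
    X,
    groups,
    family: str,
    n_quad: int = 15,
    start: np.ndarray | None = None,
) -> GLMMResult:
    """ML fit of a random-intercept GLMM.

    y: response (binary for binomial_logit); X: fixed-effects design including
    the intercept column; groups: cluster labels (random intercept per level).
    `start` optionally seeds the optimizer with a full parameter vector
    (beta..., log sigma_u[, log scale]).
    """
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {sorted(FAMILIES)}")
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    labels, gidx = np.unique(np.asarray(groups), return_inverse=True)
    order = np.argsort(gidx, kind="stable")
    y, X, gidx = y[order], X[order], gidx[order]
    starts = np.concatenate(([0], 1 + np.flatnonzero(np.diff(gidx))))
    n, p = X.shape
    nodes, wts = hermgauss(n_quad)
    log_wts = np.log(wts) - 0.5 * np.log(np.pi)

    if start is None:
        start = _default_start(y, X, family)
    args = (y, X, starts, family, nodes, log_wts, p)
    res = scipy.optimize.minimize(
        _neg_loglik, np.asarray(start, dtype=float), args=args, method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-8},
    )
    beta, sigma_u, scale = _unpack(res.x, p, family)
    return GLMMResult(
        family=family,
        beta=beta,
        sigma_u=sigma_u,
        scale=None if family == "binomial_logit" else scale,
        loglik=-float(res.fun),
        converged=bool(res.success),
        n_obs=n,
        n_groups=len(labels),
    )


def _working_response(y: np.ndarray, family: str) -> np.ndarray:
    """Response on the link scale, for least-squares starting values."""
    if family == "gaussian_log":
        return np.log(np.maximum(y, 1e-12))
    if family == "binomial_logit":
        p = np.clip(y, 0.02, 0.98)
        return np.log(p / (1 - p))
    return y


def _default_start(y: np.ndarray, X: np.ndarray, family: str) -> np.ndarray:
    """Least-squares betas on the link scale plus family-appropriate scale.

    The random-effect SD starts small relative to the link-scale residual; the
    dispersion parameter is matched to the family (residual SD for Gaussian
    links on the *response* scale, the shape lambda = mean(mu)^3 / var(resid)
    for the inverse Gaussian).
    """
    work = _working_response(y, family)
    beta0, *_ = np.linalg.lstsq(X, work, rcond=None)
    link_resid_sd = max(float(np.std(work - X @ beta0)), 1e-3)
    theta = [beta0, [np.log(0.3 * link_resid_sd + 1e-4)]]
    if family != "binomial_logit":
        if family == "gaussian_log":
            mu0 = np.exp(np.clip(X @ beta0, -50, 50))
        else:
            mu0 = X @ beta0
        resid_var = max(float(np.var(y - mu0)), 1e-12)
        if family == "inverse_gaussian_identity":
            lam0 = max(float(np.mean(np.maximum(mu0, 1e-9))) ** 3 / resid_var, 1e-6)
            theta.append([np.log(lam0)])
        else:
            theta.append([0.5 * np.log(resid_var)])
    return np.concatenate(theta)


def lrt(y, X_full, X_null, groups, family: str, n_quad: int = 15) -> dict:
    """Likelihood-ratio test between nested random-intercept GLMMs.

    The full model is refit from the null solution (padded with zeros for the
    extra columns, which must come first in X_full's extra block being at the
    *end*); the better of the warm and cold starts is kept so the statistic
    cannot go negative beyond optimizer noise.
    """
    null = fit_glmm(y, X_null, groups, family, n_quad)
    p_null, p_full = X_null.shape[1], X_full.shape[1]
    extra = p_full - p_null

    def tail(res):
        t = [np.log(max(res.sigma_u, 1e-6))]
        if family != "binomial_logit":
            t.append(np.log(max(res.scale, 1e-12)))
        return t

    # X_full must contain X_null's columns first, then the tested block
    warm = np.concatenate([null.beta, np.zeros(extra), tail(null)])
    full_a = fit_glmm(y, X_full, groups, family, n_quad, start=warm)
    full_b = fit_glmm(y, X_full, groups, family, n_quad)
    full = full_a if full_a.loglik >= full_b.loglik else full_b
    # re-polish the null from the full solution so neither side underconverges
    null_b = fit_glmm(
        y, X_null, groups, family, n_quad,
        start=np.concatenate([full.beta[:p_null], tail(full)]),
    )
    if null_b.loglik > null.loglik:
        null = null_b
    stat = max(0.0, 2.0 * (full.loglik - null.loglik))
    df = extra
    return {
        "statistic": stat,
        "df": df,
        "p": float(scipy.stats.chi2.sf(stat, df)),
        "full": full,
        "null": null,
        "converged": bool(full.converged and null.converged),
    }
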
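"""Depth-weighted beta regression for methylation proportions.

Model: y_s ~ Beta(mu_s * phi, (1 - mu_s) * phi) with logit(mu_s) = x_s' beta
(mean-precision parameterization). Proportions are pulled off the 0/1
boundary with the Smithson-Verkuilen shrinkage y' = (y (n - 1) + 0.5) / n
before fitting, since the beta likelihood is undefined at the boundary.

Observation weights are read depths normalized to sum to the number of
non-missing samples, w_s = n D_s / sum_t D_t, so that with equal depths the
fit reduces exactly to the unweighted one and standard errors stay on the
same footing as an unweighted fit of the same sample size. The weighted
log-likelihood

    l(beta, phi) = sum_s w_s log f(y'_s; mu_s, phi)

is maximized numerically (L-BFGS-B on (beta, log phi) with an analytic
gradient); the group test is a Wald test on the requested coefficient with
standard errors from the observed information (numerical Hessian at the
optimum). Because maximum-likelihood precision estimates make the plain
normal-reference Wald test anticonservative at mouse-cohort sample sizes,
a degrees-of-freedom correction is applied: the standard error is scaled
by sqrt(n / df) with df = n - (k + 1) free parameters and the statistic is
referred to a Student-t distribution with df degrees of freedom (the
analogue of using residual degrees of freedom in a linear model).
Non-convergence is reported conservatively as p = 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats
from statsmodels.tools.numdiff import approx_hess

logger = logging.getLogger(__name__)

__all__ = ["BetaRegressionFit", "fit_beta_regression", "weighted_beta_loglik", "shrink_proportions"]

_PHI_LOG_BOUNDS = (np.log(0.01), np.log(1e6))


@dataclass
class BetaRegressionFit:
    """Result of one weighted beta-regression fit.

    ``beta`` holds all mean-model coefficients on the logit scale;
    ``beta1``/``se_beta1``/``z``/``p`` refer to the tested coefficient
    (``test_index`` at fit time). ``phi`` is the beta precision.
    """

    beta: np.ndarray
    phi: float
    se_beta1: float
    z: float
    p: float
    loglik: float
    converged: bool
    n: int
    test_index: int = 1

    @property
    def beta0(self) -> float:
        return float(self.beta[0])

    @property
    def beta1(self) -> float:
        return float(self.beta[self.test_index])


def shrink_proportions(y: np.ndarray, n: int | None = None) -> np.ndarray:
    """Smithson-Verkuilen boundary shrinkage y' = (y (n - 1) + 0.5) / n."""
    y = np.asarray(y, dtype=float)
    if n is None:
        n = len(y)
    return (y * (n - 1) + 0.5) / n


def weighted_beta_loglik(
    beta: np.ndarray, phi: float, y: np.ndarray, X: np.ndarray, w: np.ndarray
) -> float:
    """Weighted beta log-likelihood at (beta, phi); y must be in (0, 1)."""
    eta = X @ beta
    mu = special.expit(eta)
    a = mu * phi
    b = (1.0 - mu) * phi
    ll = (
        special.gammaln(phi)
        - special.gammaln(a)
        - special.gammaln(b)
        + (a - 1.0) * np.log(y)
        + (b - 1.0) * np.log1p(-y)
    )
    return float(np.sum(w * ll))


def _negll_and_grad(theta, y, X, w, logy, log1my):
    beta = theta[:-1]
    phi = np.exp(theta[-1])
    eta = X @ beta
    # keep mu strictly inside (0, 1); extreme eta during line search would
    # otherwise produce NaNs in the digamma terms
    mu = np.clip(special.expit(eta), 1e-12, 1.0 - 1e-12)
    a = mu * phi
    b = (1.0 - mu) * phi
    ll = (
        special.gammaln(phi) - special.gammaln(a) - special.gammaln(b)
        + (a - 1.0) * logy + (b - 1.0) * log1my
    )
    # d l / d mu and chain rule through the logit link
    ystar = logy - log1my
    mustar = special.digamma(a) - special.digamma(b)
    dl_dmu = w * phi * (ystar - mustar)
    gbeta = X.T @ (dl_dmu * mu * (1.0 - mu))
    dl_dphi = w * (
        special.digamma(phi)
        - mu * special.digamma(a)
        - (1.0 - mu) * special.digamma(b)
        + mu * logy
        + (1.0 - mu) * log1my
    )
    glogphi = float(np.sum(dl_dphi)) * phi
    grad = np.concatenate([gbeta, [glogphi]])
    return -float(np.sum(w * ll)), -grad


def fit_beta_regression(
    y: np.ndarray,
    weights: np.ndarray,
    X: np.ndarray,
    test_index: int = 1,
) -> BetaRegressionFit:
    """Fit the weighted beta regression and Wald-test one coefficient.

    Parameters
    ----------
    y : per-sample proportions in [0, 1] (NaN entries are dropped together
        with their weights and design rows).
    weights : per-sample pooled read depths (>= 0); normalized internally.
    X : (n, k) design matrix; column ``test_index`` is the tested
        coefficient (the group indicator, or a continuous predictor).
    """
    y = np.asarray(y, dtype=float)
    weights = np.asarray(weights, dtype=float)
    X = np.asarray(X, dtype=float)
    ok = ~np.isnan(y) & (weights > 0)
    y, weights, X = y[ok], weights[ok], X[ok]
    n, k = X.shape
    if n < k + 1:
        return _failed_fit(k, n, test_index, "too few samples")

    yp = shrink_proportions(y, n)
    w = n * weights / weights.sum()
    logy = np.log(yp)
    log1my = np.log1p(-yp)

    # starting values: weighted least squares on logit(y'), method-of-moments phi
    z = special.logit(yp)
    W = np.diag(w)
    try:
        beta0 = np.linalg.solve(X.T @ W @ X, X.T @ W @ z)
    except np.linalg.LinAlgError:
        return _failed_fit(k, n, test_index, "singular design")
    mu0 = special.expit(X @ beta0)
    resid_var = float(np.average((yp - mu0) ** 2, weights=w))
    if resid_var <= 0:
        resid_var = 1e-6
    phi0 = float(np.clip(np.mean(mu0 * (1 - mu0)) / resid_var - 1.0, 0.5, 1e4))
    theta0 = np.concatenate([beta0, [np.log(phi0)]])

    bounds = [(None, None)] * k + [_PHI_LOG_BOUNDS]
    res = optimize.minimize(
        _negll_and_grad,
        theta0,
        args=(yp, X, w, logy, log1my),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-8},
    )
    beta = res.x[:-1]
    phi = float(np.exp(res.x[-1]))
    loglik = -float(res.fun)
    if not np.isfinite(loglik):
        return _failed_fit(k, n, test_index, "non-finite likelihood")

    # observed information at the optimum; the beta block of the inverse is
    # invariant to the log-phi reparameterization at a stationary point
    try:
        H = approx_hess(res.x, lambda t: _negll_and_grad(t, yp, X, w, logy, log1my)[0])
        cov = np.linalg.inv(H)
        var1 = float(cov[test_index, test_index])
    except np.linalg.LinAlgError:
        var1 = np.nan
    if not np.isfinite(var1) or var1 <= 0:
        return _failed_fit(k, n, test_index, "singular information", beta=beta, phi=phi, loglik=loglik)

    df = n - (k + 1)
    if df < 1:
        return _failed_fit(k, n, test_index, "no residual degrees of freedom",
                           beta=beta, phi=phi, loglik=loglik)
    se = float(np.sqrt(var1) * np.sqrt(n / df))
    zstat = float(beta[test_index] / se)
    p = float(2.0 * stats.t.sf(abs(zstat), df))
    return BetaRegressionFit(
        beta=beta, phi=phi, se_beta1=se, z=zstat, p=p,
        loglik=loglik, converged=bool(res.success), n=n, test_index=test_index,
    )


def _failed_fit(k, n, test_index, reason, beta=None, phi=np.nan, loglik=np.nan) -> BetaRegressionFit:
    logger.debug("beta regression not testable: %s", reason)
    return BetaRegressionFit(
        beta=np.full(k, np.nan) if beta is None else beta,
        phi=phi, se_beta1=np.nan, z=np.nan, p=1.0,
        loglik=loglik, converged=False, n=n, test_index=test_index,
    )
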
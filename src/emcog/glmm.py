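"""Maximum-likelihood random-intercept GLMMs via Gauss-Hermite quadrature.

Fits models of the form

    g(E[y_ij]) = x_ij' beta + u_i,     u_i ~ N(0, sigma^2)

for binomial (logit) and Poisson (log) families.  The marginal
log-likelihood integrates the random intercept out with *adaptive*
Gauss-Hermite quadrature: for each cluster the nodes are centred at
the posterior mode of u_i (found by a vectorised 1-D Newton iteration)
and scaled by the Laplace curvature there, so a modest number of nodes
is accurate even for sharp Poisson integrands.  Fixed effects are
estimated by BFGS with Wald standard errors from the numerical Hessian
at the optimum.

This is the workhorse behind the mixed-effects logistic fatigue model
(probability of missing a session as a function of study day) and the
mixed Poisson practice model for count-scored outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special
from statsmodels.tools.numdiff import approx_hess1

FAMILIES = ("binomial", "poisson")


@dataclass
class GLMMResult:
    params: np.ndarray          # fixed effects
    bse: np.ndarray
    pvalues: np.ndarray
    exog_names: list[str]
    re_sd: float                # random-intercept SD
    llf: float
    aic: float
    n_obs: int
    n_groups: int
    converged: bool
    family: str

    def summary_dict(self) -> dict:
        return {
            "family": self.family,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "converged": self.converged,
            "re_sd": self.re_sd,
            "llf": self.llf,
            "aic": self.aic,
            "fixed_effects": {
                name: {"estimate": float(b), "se": float(s), "p": float(p)}
                for name, b, s, p in zip(self.exog_names, self.params,
                                         self.bse, self.pvalues)
            },
        }


class SeparationError(RuntimeError):
    """The binary outcome is constant; no slope is estimable."""


def _obs_loglik(y, eta, family):
    """Pointwise log-likelihood, shape (n_obs, n_nodes)."""
    if family == "binomial":
        # log p(y|eta) = y*eta - log(1+exp(eta)), stable via logaddexp
        return y[:, None] * eta - np.logaddexp(0.0, eta)
    # poisson: y*eta - exp(eta) - log(y!)
    return y[:, None] * eta - np.exp(eta) - special.gammaln(y + 1.0)[:, None]


def fit_glmm_ri(
    endog,
    exog,
    groups,
    family: str = "binomial",
    exog_names: list[str] | None = None,
    n_points: int = 25,
) -> GLMMResult:
    """Fit a random-intercept GLMM by marginal maximum likelihood.

    Parameters
    ----------
    endog : (n,) response (0/1 for binomial, counts for poisson)
    exog : (n, p) design including the intercept column
    groups : (n,) cluster labels
    """
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}")
    y = np.asarray(endog, dtype=float)
    X = np.asarray(exog, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    codes, uniques = _factorize(np.asarray(groups))
    n_groups = len(uniques)
    if exog_names is None:
        exog_names = [f"x{i}" for i in range(p)]

    if family == "binomial" and (y.min() == y.max()):
        raise SeparationError("outcome is constant (all 0 or all 1)")

    nodes, weights = np.polynomial.hermite.hermgauss(n_points)
    log_adapt_w = np.log(weights) + nodes ** 2  # adaptive-GH weight term

    def _posterior_modes(xb, sd):
        """Vectorised Newton search for each cluster's mode of
        sum_j loglik(u) - u^2/(2 sd^2), plus the Laplace scale there."""
        u = np.zeros(n_groups)
        for _ in range(50):
            eta = xb + u[codes]
            mu = special.expit(eta) if family == "binomial" else np.exp(eta)
            var = mu * (1.0 - mu) if family == "binomial" else mu
            grad = np.bincount(codes, y - mu, n_groups) - u / sd**2
            hess = -np.bincount(codes, var, n_groups) - 1.0 / sd**2
            step = grad / hess
            u = u - np.clip(step, -5.0, 5.0)
            if np.max(np.abs(step)) < 1e-9:
                break
        eta = xb + u[codes]
        mu = special.expit(eta) if family == "binomial" else np.exp(eta)
        var = mu * (1.0 - mu) if family == "binomial" else mu
        curv = np.bincount(codes, var, n_groups) + 1.0 / sd**2
        return u, 1.0 / np.sqrt(curv)

    def nll(theta):
        beta, log_sd = theta[:p], theta[p]
        sd = np.exp(log_sd)
        xb = X @ beta
        mode, scale = _posterior_modes(xb, sd)
        # u evaluated at mode_i + sqrt(2) * scale_i * node_k
        u_nodes = mode[:, None] + np.sqrt(2.0) * scale[:, None] * nodes[None, :]
        eta = xb[:, None] + u_nodes[codes]
        ll_obs = _obs_loglik(y, eta, family)              # (n, K)
        ll_grp = np.zeros((n_groups, n_points))
        np.add.at(ll_grp, codes, ll_obs)
        log_prior = (-0.5 * u_nodes**2 / sd**2 - np.log(sd)
                     - 0.5 * np.log(2.0 * np.pi))
        integrand = ll_grp + log_prior + log_adapt_w[None, :]
        ll = special.logsumexp(integrand, axis=1) \
            + 0.5 * np.log(2.0) + np.log(scale)
        return -float(np.sum(ll))

    theta0 = np.zeros(p + 1)
    if family == "poisson":
        theta0[0] = np.log(max(y.mean(), 0.1))
    theta0[p] = np.log(0.5)
    res = optimize.minimize(nll, theta0, method="BFGS",
                            options={"maxiter": 500, "gtol": 1e-6})
    theta = res.x

    # Wald SEs from the numerical Hessian of the negative log-likelihood
    try:
        hess = approx_hess1(theta, nll)
        cov = np.linalg.inv(hess)
        se_all = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se_all = np.full(p + 1, np.nan)
    bse = se_all[:p]
    from scipy import stats
    z = np.divide(theta[:p], bse, out=np.full(p, np.nan), where=bse > 0)
    pvals = 2.0 * stats.norm.sf(np.abs(z))

    llf = -res.fun
    k = p + 1
    return GLMMResult(
        params=theta[:p], bse=bse, pvalues=pvals, exog_names=list(exog_names),
        re_sd=float(np.exp(theta[p])), llf=llf, aic=2 * k - 2 * llf,
        n_obs=n, n_groups=n_groups, converged=bool(res.success), family=family,
    )


def _factorize(values):
    uniques, codes = np.unique(values, return_inverse=True)
    return codes, uniques
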
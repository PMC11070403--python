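"""Maximum-likelihood random-intercept models used by the determinants
stage.

The logistic mixed model (binary response, one Gaussian random intercept
per group) is fit by direct maximisation of the marginal likelihood,
integrating the random effect with Gauss-Hermite quadrature; this yields a
true ML deviance, so AIC comparisons across fixed-effect subsets are
well defined.  The linear mixed model is delegated to statsmodels'
``MixedLM`` with ``reml=False`` for the same reason.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import logsumexp

__all__ = ["GlmmFit", "fit_logistic_rim", "fit_linear_rim"]


@dataclass
class GlmmFit:
    """A fitted random-intercept model (logit or Gaussian response)."""

    beta: np.ndarray          # fixed-effect coefficients (incl. intercept)
    se: np.ndarray
    tau2: float               # random-intercept variance
    sigma2: float             # residual variance (NaN for logit)
    loglik: float
    n_params: int
    converged: bool

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik

    @property
    def zvalues(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.beta / self.se

    @property
    def pvalues(self) -> np.ndarray:
        from scipy.stats import norm
        return 2.0 * norm.sf(np.abs(self.zvalues))


def _group_slices(groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(groups, kind="stable")
    sorted_groups = groups[order]
    starts = np.flatnonzero(np.r_[True, sorted_groups[1:] != sorted_groups[:-1]])
    return order, starts


def fit_logistic_rim(y: np.ndarray, X: np.ndarray, groups: np.ndarray,
                     n_quad: int = 25) -> GlmmFit:
    """ML logistic regression with a per-group Gaussian random intercept.

    The marginal log-likelihood sums, over groups g, the log of
    ``int prod_i Bernoulli(y_i | logit^-1(x_i'b + u)) N(u; 0, tau^2) du``
    evaluated with ``n_quad``-point Gauss-Hermite quadrature.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    groups = np.asarray(groups)
    order, starts = _group_slices(groups)
    ys, Xs = y[order], X[order]
    nodes, qw = hermgauss(n_quad)
    log_qw = np.log(qw) - 0.5 * np.log(np.pi)
    p = X.shape[1]

    group_index = np.repeat(np.arange(len(starts)),
                            np.diff(np.r_[starts, len(ys)]))
    sq2 = np.sqrt(2.0)

    def negll_grad(params: np.ndarray) -> tuple[float, np.ndarray]:
        beta, tau = params[:p], params[p]
        eta = Xs @ beta
        A = eta[:, None] + sq2 * tau * nodes[None, :]
        # log sigmoid(A) and log(1 - sigmoid(A)), numerically stable
        ll_obs = np.where(ys[:, None] > 0.5,
                          -np.logaddexp(0.0, -A), -np.logaddexp(0.0, A))
        grp = np.add.reduceat(ll_obs, starts, axis=0) + log_qw[None, :]
        lse = logsumexp(grp, axis=1)                       # (G,)
        post = np.exp(grp - lse[:, None])                  # (G, Q) weights
        W = post[group_index]                              # (n, Q)
        resid = ys[:, None] - 1.0 / (1.0 + np.exp(-A))
        wr = W * resid
        g_beta = -(Xs.T @ wr.sum(axis=1))
        g_tau = -sq2 * float((wr * nodes[None, :]).sum())
        return -float(lse.sum()), np.r_[g_beta, g_tau]

    def negll(params: np.ndarray) -> float:
        return negll_grad(params)[0]

    # warm start at the ordinary logistic fit (IRLS), tau = 0.5
    beta0 = np.zeros(p)
    try:
        import statsmodels.api as sm
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glm = sm.GLM(ys, Xs, family=sm.families.Binomial()).fit()
        if np.all(np.isfinite(glm.params)) and np.max(np.abs(glm.params)) < 20:
            beta0 = np.asarray(glm.params, float)
    except Exception:  # separation etc.; the cold start still works
        pass
    x0 = np.r_[beta0, 0.5]
    bounds = [(None, None)] * p + [(0.0, 20.0)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        best = minimize(negll_grad, x0, jac=True, method="L-BFGS-B",
                        bounds=bounds,
                        options={"maxiter": 500, "ftol": 1e-12,
                                 "gtol": 1e-8})
        retry = minimize(negll_grad, np.r_[beta0, 1e-3], jac=True,
                         method="L-BFGS-B", bounds=bounds,
                         options={"maxiter": 500, "ftol": 1e-12,
                                  "gtol": 1e-8})
        if retry.fun < best.fun:
            best = retry
    beta = best.x[:p]
    tau = abs(best.x[p])
    se = _hessian_se(negll, best.x)[:p]
    if not np.all(np.isfinite(se)):
        # tau on the boundary can make the joint Hessian singular;
        # condition on the estimated tau for the coefficient SEs
        se = _hessian_se(lambda b: negll(np.r_[b, tau]), best.x[:p].copy())
    return GlmmFit(beta=beta, se=se, tau2=tau ** 2, sigma2=float("nan"),
                   loglik=-float(best.fun), n_params=p + 1,
                   converged=bool(np.isfinite(best.fun)))


def _hessian_se(fun, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    """Standard errors from a central-difference Hessian; NaN on failure."""
    n = len(x)
    H = np.zeros((n, n))
    f0 = fun(x)
    for i in range(n):
        for j in range(i, n):
            xi = x.copy()
            if i == j:
                xi[i] += eps
                fp = fun(xi)
                xi[i] -= 2 * eps
                fm = fun(xi)
                H[i, i] = (fp - 2 * f0 + fm) / eps ** 2
            else:
                xpp = x.copy(); xpp[[i, j]] += eps
                xpm = x.copy(); xpm[i] += eps; xpm[j] -= eps
                xmp = x.copy(); xmp[i] -= eps; xmp[j] += eps
                xmm = x.copy(); xmm[[i, j]] -= eps
                H[i, j] = H[j, i] = (fun(xpp) - fun(xpm) - fun(xmp)
                                     + fun(xmm)) / (4 * eps ** 2)
    try:
        cov = np.linalg.inv(H)
        d = np.diag(cov).copy()
        d[d < 0] = np.nan
        return np.sqrt(d)
    except np.linalg.LinAlgError:
        return np.full(n, np.nan)


def fit_linear_rim(y: np.ndarray, X: np.ndarray,
                   groups: np.ndarray) -> GlmmFit:
    """ML linear mixed model with a per-group random intercept.

    The marginal covariance of group g is ``sigma^2 (I + lambda J)`` with
    ``lambda = tau^2 / sigma^2``; beta and sigma^2 have closed forms given
    lambda (Woodbury inverse of the compound-symmetric block), so the
    profile likelihood is maximised over the single ratio lambda.  A small
    floor on sigma^2 keeps the noiseless limit well defined.
    """
    from scipy.optimize import minimize_scalar

    y = np.asarray(y, float)
    X = np.asarray(X, float)
    groups = np.asarray(groups)
    order, starts = _group_slices(groups)
    ys, Xs = y[order], X[order]
    bounds_idx = np.r_[starts, len(ys)]
    sizes = np.diff(bounds_idx)
    n, p = Xs.shape
    SIGMA2_FLOOR = 1e-10

    def profile(lam: float):
        # GLS with block inverse I - lam/(1+lam*n_g) J per group
        XtX = np.zeros((p, p))
        Xty = np.zeros(p)
        for g, (a, b) in enumerate(zip(bounds_idx[:-1], bounds_idx[1:])):
            Xg, yg = Xs[a:b], ys[a:b]
            c = lam / (1.0 + lam * sizes[g])
            xs, ysum = Xg.sum(axis=0), yg.sum()
            XtX += Xg.T @ Xg - c * np.outer(xs, xs)
            Xty += Xg.T @ yg - c * xs * ysum
        beta = np.linalg.solve(XtX, Xty)
        q = 0.0
        logdet = 0.0
        for g, (a, b) in enumerate(zip(bounds_idx[:-1], bounds_idx[1:])):
            r = ys[a:b] - Xs[a:b] @ beta
            c = lam / (1.0 + lam * sizes[g])
            q += r @ r - c * r.sum() ** 2
            logdet += np.log1p(lam * sizes[g])
        sigma2 = max(q / n, SIGMA2_FLOOR)
        ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + q / sigma2)
        return ll, beta, sigma2, XtX

    def neg(log_lam: float) -> float:
        return -profile(np.exp(log_lam))[0]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = minimize_scalar(neg, bounds=(-12.0, 12.0), method="bounded",
                              options={"xatol": 1e-8})
    candidates = [np.exp(res.x), 0.0]
    best = max((profile(lam) + (lam,) for lam in candidates),
               key=lambda t: t[0])
    ll, beta, sigma2, XtX = best[:4]
    lam = best[4]
    tau2 = lam * sigma2
    try:
        cov_beta = sigma2 * np.linalg.inv(XtX)
        se = np.sqrt(np.maximum(np.diag(cov_beta), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return GlmmFit(beta=beta, se=se, tau2=float(tau2), sigma2=float(sigma2),
                   loglik=float(ll), n_params=p + 2, converged=True)
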
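"""Stochastic frontier estimation of the self-thinning upper boundary.

The frontier model treats the size–density line as a production boundary:

    lnV_j = a + b lnN_j + v_j - u_j,    v_j ~ N(0, sigma_v^2),  u_j >= 0,

with half-normal inefficiency ``u_j ~ |N(0, sigma_u^2)|``.  The composed
error ``e = v - u`` has the classic skew-normal-type density

    f(e) = (2 / sigma) phi(e / sigma) Phi(-e lambda / sigma),

with ``sigma^2 = sigma_u^2 + sigma_v^2`` and ``lambda = sigma_u /
sigma_v``.  Maximum likelihood over ``(a, b, sigma, lambda)`` pushes the
fitted line toward the upper envelope of the point cloud, which is what
makes the frontier a natural competitor to hierarchical mean-line fits for
maximum size–density estimation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .evaluate import rmse_from_residuals
from .gibbs import ols_line
from .stand_data import ModelDataset

__all__ = ["SFFResult", "sff_loglik", "fit_sff"]

log = logging.getLogger(__name__)

# likelihood-ratio guard: if 2*(logL(lambda_hat) - logL(0)) falls below this
# (the 10% chi-bar-squared critical value for a boundary test), the one-sided
# component is indistinguishable from zero and the OLS-equivalent fit is
# returned instead of a spuriously shifted frontier
_LR_EPS = 1.642


@dataclass(frozen=True)
class SFFResult:
    """Fitted frontier line and composed-error components."""

    intercept_a: float
    slope_b: float
    sigma_v: float
    sigma_u: float
    loglik: float
    se_a: float
    se_b: float
    rmse: float           # conditional-mean predictions (mean-zero residuals)
    rmse_frontier: float  # raw frontier-line predictions
    converged: bool = True
    degenerate: bool = False  # True when the fit collapsed to OLS (lambda ~ 0)

    @property
    def lam(self) -> float:
        return self.sigma_u / self.sigma_v

    @property
    def sigma2(self) -> float:
        return self.sigma_u**2 + self.sigma_v**2

    def to_frame(self):
        """Report layout: parameter, estimate, SE rows plus fit statistics."""
        import pandas as pd

        return pd.DataFrame(
            {
                "estimate": [self.intercept_a, self.slope_b, self.sigma_v,
                             self.sigma_u, self.lam, self.loglik, self.rmse],
                "se": [self.se_a, self.se_b, np.nan, np.nan, np.nan, np.nan, np.nan],
            },
            index=["a", "b", "sigma_v", "sigma_u", "lambda", "loglik", "rmse"],
        )


def sff_loglik(a: float, b: float, sigma: float, lam: float,
               dataset: ModelDataset) -> float:
    """Log-likelihood of the normal–half-normal frontier model.

    With ``e_j = lnV_j - a - b lnN_j``:

        sum_j [ ln 2 - ln sigma + log phi(e_j/sigma) + log Phi(-e_j lambda/sigma) ].

    At ``lam = 0`` this reduces to the ordinary normal log-likelihood with
    SD ``sigma`` (``Phi(0) = 1/2`` cancels the ``ln 2``).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    e = dataset.lnV - a - b * dataset.lnN
    return float(np.sum(
        np.log(2.0) - np.log(sigma)
        + stats.norm.logpdf(e / sigma)
        + stats.norm.logcdf(-e * lam / sigma)
    ))


def _neg_loglik(theta: np.ndarray, dataset: ModelDataset) -> float:
    a, b, log_sigma, log_lam = theta
    sigma = np.exp(log_sigma)
    lam = np.exp(log_lam)
    if not np.isfinite(sigma) or not np.isfinite(lam):
        return np.inf
    return -sff_loglik(a, b, sigma, lam, dataset)


def _numerical_hessian(f, theta: np.ndarray, h: float = 1e-4) -> np.ndarray:
    k = len(theta)
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h
            ej = np.zeros(k); ej[j] = h
            H[i, j] = H[j, i] = (
                f(theta + ei + ej) - f(theta + ei - ej)
                - f(theta - ei + ej) + f(theta - ei - ej)
            ) / (4.0 * h * h)
    return H


def _ols_equivalent(dataset: ModelDataset, reason: str) -> SFFResult:
    """Degenerate (lambda = 0) fit: the frontier collapses to OLS."""
    a0, b0, s2, cov = ols_line(dataset)
    resid = dataset.lnV - a0 - b0 * dataset.lnN
    sigma_mle = float(np.sqrt(np.mean(resid**2)))
    ll = sff_loglik(a0, b0, sigma_mle, 0.0, dataset)
    warnings.warn(f"frontier inefficiency indistinguishable from zero ({reason}); "
                  "returning OLS-equivalent fit", stacklevel=3)
    r = dataset.lnV - a0 - b0 * dataset.lnN
    return SFFResult(
        intercept_a=a0, slope_b=b0, sigma_v=sigma_mle, sigma_u=0.0,
        loglik=ll, se_a=float(np.sqrt(cov[0, 0])), se_b=float(np.sqrt(cov[1, 1])),
        rmse=rmse_from_residuals(r), rmse_frontier=rmse_from_residuals(r),
        converged=True, degenerate=True,
    )


def fit_sff(dataset: ModelDataset, init: np.ndarray | None = None,
            *, n_restarts: int = 5, seed: int = 0) -> SFFResult:
    """Maximum-likelihood frontier fit.

    Starts from the OLS line with a corrected-OLS guess for ``lambda``
    (driven by the sign of the residual skewness: a genuine upper frontier
    leaves negatively skewed residuals).  On non-convergence the optimizer
    restarts from deterministically jittered points.  Standard errors come
    from the inverse observed information.

    Two prediction conventions are reported: ``rmse`` uses conditional-mean
    predictions ``a + b lnN - sigma_u sqrt(2/pi)`` (mean-zero residuals,
    commensurable with mean-line fits) and ``rmse_frontier`` uses the raw
    frontier line.

    Raises
    ------
    ValueError
        If the dataset has fewer than 4 observations.
    RuntimeError
        If no start converges.
    """
    if dataset.n_obs < 4:
        raise ValueError("frontier fit needs at least 4 observations")
    a0, b0, s2, _ = ols_line(dataset)
    resid = dataset.lnV - a0 - b0 * dataset.lnN
    skew = float(stats.skew(resid))
    if skew >= 0:
        # wrong-sign skew: the one-sided component would be estimated at zero
        return _ols_equivalent(dataset, f"residual skewness {skew:.3f} >= 0")

    sigma0 = float(np.sqrt(np.mean(resid**2)))
    if init is not None:
        theta0 = np.asarray(init, dtype=float)
    else:
        theta0 = np.array([a0, b0, np.log(sigma0), 0.0])

    rng = np.random.default_rng(seed)
    best = None
    for attempt in range(n_restarts + 1):
        start = theta0 if attempt == 0 else theta0 + rng.normal(0, 0.1, size=4)
        res = optimize.minimize(_neg_loglik, start, args=(dataset,), method="BFGS",
                                options={"maxiter": 2000})
        if not res.success:
            # BFGS often stops with "precision loss" at a flat optimum;
            # a simplex polish from its endpoint settles the point
            polish = optimize.minimize(_neg_loglik, res.x, args=(dataset,),
                                       method="Nelder-Mead",
                                       options={"xatol": 1e-10, "fatol": 1e-12,
                                                "maxiter": 4000})
            if polish.fun <= res.fun:
                res = polish
        if best is None or res.fun < best.fun:
            best = res
        if res.success:
            break
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("frontier fit failed to converge after restarts")
    if not best.success and attempt == n_restarts:
        log.warning("frontier optimizer reported non-convergence: %s", best.message)

    a, b = float(best.x[0]), float(best.x[1])
    sigma = float(np.exp(best.x[2]))
    lam = float(np.exp(best.x[3]))
    ll = -float(best.fun)

    # boundary test: is the one-sided component supported by the likelihood?
    ll0 = sff_loglik(a0, b0, sigma0, 0.0, dataset)
    if lam < 1e-2 or 2.0 * (ll - ll0) < _LR_EPS:
        return _ols_equivalent(dataset, f"LR = {2.0 * (ll - ll0):.3f}")

    H = _numerical_hessian(lambda t: _neg_loglik(t, dataset), best.x)
    try:
        cov = np.linalg.inv(H)
        se_a, se_b = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    except np.linalg.LinAlgError:
        se_a = se_b = np.nan

    sigma_u = sigma * lam / np.sqrt(1.0 + lam**2)
    sigma_v = sigma / np.sqrt(1.0 + lam**2)
    yhat_front = a + b * dataset.lnN
    shift = sigma_u * np.sqrt(2.0 / np.pi)  # E[u] of the half-normal
    return SFFResult(
        intercept_a=a, slope_b=b, sigma_v=sigma_v, sigma_u=sigma_u,
        loglik=ll,
        se_a=se_a, se_b=se_b,
        rmse=rmse_from_residuals(dataset.lnV - (yhat_front - shift)),
        rmse_frontier=rmse_from_residuals(dataset.lnV - yhat_front),
        converged=bool(best.success),
        degenerate=False,
    )
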
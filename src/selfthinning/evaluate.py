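"""Posterior summaries, DIC, RMSE and the variance partition.

The deviance underlying DIC is the *conditional* one: the normal
likelihood of lnV given the line, with the plot-level random effects
plugged in as parameters.  ``pD = Dbar - Dhat`` with ``Dhat`` evaluated at
the posterior *mean* of every parameter (means, not medians), and
``DIC = Dbar + pD``.

RMSE uses an n-1 divisor: ``sqrt(sum (y - yhat)^2 / (n - 1))``.  In the
default "conditional" mode the prediction for an observation includes the
posterior-mean random effect of its plot; "marginal" mode uses the
population line only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gibbs import PosteriorChains
from .stand_data import ModelDataset

__all__ = ["FitSummary", "summarize", "dic", "rmse", "variance_partition",
           "variance_partition_from_medians", "gelman_rubin"]

_CHUNK = 4096  # draws per block when evaluating per-draw deviances


@dataclass(frozen=True)
class FitSummary:
    """Parameter table plus model-level fit statistics."""

    table: pd.DataFrame  # rows = parameters; cols = mean, sd, median, lower, higher
    dbar: float | None = None
    dhat: float | None = None
    p_d: float | None = None
    dic: float | None = None
    rmse: float | None = None

    def to_frame(self) -> pd.DataFrame:
        """Export in a report layout: parameter rows then model-level rows."""
        df = self.table.copy()
        extra = {}
        for name, val in [("DIC", self.dic), ("Dbar", self.dbar), ("Dhat", self.dhat),
                          ("pD", self.p_d), ("RMSE", self.rmse)]:
            if val is not None:
                extra[name] = val
        for name, val in extra.items():
            df.loc[name] = [val, np.nan, np.nan, np.nan, np.nan]
        return df


def _summary_row(draws: np.ndarray) -> list[float]:
    q_lo, med, q_hi = np.quantile(draws, [0.025, 0.5, 0.975])
    return [float(np.mean(draws)), float(np.std(draws, ddof=1)) if draws.size > 1 else 0.0,
            float(med), float(q_lo), float(q_hi)]


def summarize(chains: PosteriorChains, *, include_random_effects: bool = False) -> FitSummary:
    """Posterior mean, SD, median and 95% credible bounds per parameter.

    Draws are pooled across chains; quantiles use linear interpolation of
    order statistics.
    """
    if chains.n_draws == 0:
        raise ValueError("empty chains")
    rows, names = [], []
    for name, draws in chains.parameters().items():
        names.append(name)
        rows.append(_summary_row(draws))
    if include_random_effects:
        for uname, uarr, flag in [("u0", chains.u0, chains.form.has_u0),
                                  ("u1", chains.u1, chains.form.has_u1)]:
            if not flag:
                continue
            for k, pid in enumerate(chains.plot_ids):
                names.append(f"{uname}[{pid}]")
                rows.append(_summary_row(uarr[:, :, k].reshape(-1)))
    table = pd.DataFrame(rows, index=names,
                         columns=["mean", "sd", "median", "lower", "higher"])
    return FitSummary(table=table)


def _conditional_loglik(a, b, u0, u1, var_eps, dataset: ModelDataset) -> np.ndarray:
    """Log-likelihood of the dataset per draw (vectorized over draws).

    Parameters are arrays over draws: ``a, b, var_eps`` shape (m,),
    ``u0, u1`` shape (m, n_plots).
    """
    g = dataset.plot_index - 1
    x, y = dataset.lnN, dataset.lnV
    mu = (a[:, None] + u0[:, g]) + (b[:, None] + u1[:, g]) * x[None, :]
    ssr = np.sum((y[None, :] - mu) ** 2, axis=1)
    n = dataset.n_obs
    ll = -0.5 * n * np.log(2.0 * np.pi * var_eps) - ssr / (2.0 * var_eps)
    return ll


def dic(chains: PosteriorChains, dataset: ModelDataset) -> tuple[float, float, float, float]:
    """Deviance information criterion on the conditional deviance.

    Returns ``(Dbar, Dhat, pD, DIC)`` where ``Dbar`` is the posterior mean
    of ``D = -2 log p(data | theta)``, ``Dhat`` the deviance at the
    posterior mean of all parameters (random effects included), ``pD =
    Dbar - Dhat`` and ``DIC = Dbar + pD``.
    """
    a = chains.a.reshape(-1)
    b = chains.b.reshape(-1)
    u0 = chains.u0.reshape(-1, chains.u0.shape[-1])
    u1 = chains.u1.reshape(-1, chains.u1.shape[-1])
    ve = chains.var_eps.reshape(-1)
    m = a.size
    dev_sum = 0.0
    for lo in range(0, m, _CHUNK):
        hi = min(lo + _CHUNK, m)
        ll = _conditional_loglik(a[lo:hi], b[lo:hi], u0[lo:hi], u1[lo:hi], ve[lo:hi], dataset)
        if not np.all(np.isfinite(ll)):
            bad = lo + int(np.argmin(np.isfinite(ll)))
            raise FloatingPointError(f"non-finite likelihood at draw {bad}")
        dev_sum += float(np.sum(-2.0 * ll))
    dbar = dev_sum / m
    ll_hat = _conditional_loglik(
        np.array([a.mean()]), np.array([b.mean()]),
        u0.mean(axis=0)[None, :], u1.mean(axis=0)[None, :],
        np.array([ve.mean()]), dataset,
    )[0]
    dhat = float(-2.0 * ll_hat)
    p_d = dbar - dhat
    return dbar, dhat, p_d, dbar + p_d


def rmse(chains: PosteriorChains, dataset: ModelDataset, mode: str = "conditional") -> float:
    """Root mean square error of posterior-mean predictions, n-1 divisor.

    ``mode="conditional"`` adds each plot's posterior-mean random effect to
    its predictions; ``mode="marginal"`` uses the population line alone.
    """
    if dataset.n_obs < 2:
        raise ValueError("RMSE needs at least 2 observations (n-1 divisor)")
    if mode not in ("conditional", "marginal"):
        raise ValueError("mode must be 'conditional' or 'marginal'")
    a_bar = float(chains.a.mean())
    b_bar = float(chains.b.mean())
    g = dataset.plot_index - 1
    if mode == "conditional":
        u0_bar = chains.u0.reshape(-1, chains.u0.shape[-1]).mean(axis=0)
        u1_bar = chains.u1.reshape(-1, chains.u1.shape[-1]).mean(axis=0)
    else:
        u0_bar = np.zeros(len(chains.plot_ids))
        u1_bar = np.zeros(len(chains.plot_ids))
    yhat = (a_bar + u0_bar[g]) + (b_bar + u1_bar[g]) * dataset.lnN
    return rmse_from_residuals(dataset.lnV - yhat)


def rmse_from_residuals(residuals: np.ndarray) -> float:
    """``sqrt(sum r^2 / (n - 1))`` — the n-1 divisor convention."""
    r = np.asarray(residuals, dtype=float)
    if r.size < 2:
        raise ValueError("RMSE needs at least 2 residuals (n-1 divisor)")
    return float(np.sqrt(np.sum(r**2) / (r.size - 1)))


def variance_partition_from_medians(
    between_median: float, total_median: float
) -> tuple[float, float]:
    """Percent split of total variation into between- and within-plot parts.

    ``between_median`` is the posterior median of the between-plot variance
    component (sigma0^2 or sigma1^2); ``total_median`` the posterior median
    taken as the total variation.  Returns ``(between %, within %)``
    summing to exactly 100.
    """
    if total_median <= 0:
        raise ValueError("total variation must be positive")
    if between_median < 0 or between_median > total_median:
        raise ValueError("between-component median must lie in [0, total]")
    between = 100.0 * between_median / total_median
    return between, 100.0 - between


def variance_partition(
    chains: PosteriorChains, *, total: str = "residual"
) -> tuple[float, float]:
    """Between- vs within-plot share of variation, from posterior medians.

    Medians are taken component-wise.  ``total="residual"`` (default)
    follows the reporting convention in which the residual-variance median
    is read as the total variation — sensible here because the between
    component's posterior is heavily right-skewed with a median an order of
    magnitude below the residual one.  ``total="sum"`` instead divides by
    the sum of the between and residual medians.  Both raw medians are
    available through :func:`summarize` for recomputing alternatives.
    """
    if chains.var_u0 is None and chains.var_u1 is None:
        raise ValueError("variance partition needs a random-effects model form")
    between = 0.0
    if chains.var_u0 is not None:
        between += float(np.median(chains.var_u0))
    if chains.var_u1 is not None:
        between += float(np.median(chains.var_u1))
    resid = float(np.median(chains.var_eps))
    if total == "residual":
        denom = resid
        between = min(between, denom)  # guard: convention assumes between << residual
    elif total == "sum":
        denom = between + resid
    else:
        raise ValueError("total must be 'residual' or 'sum'")
    return variance_partition_from_medians(between, denom)


def gelman_rubin(chains: PosteriorChains) -> dict[str, float]:
    """Split-R-hat convergence diagnostic per scalar parameter (via ArviZ)."""
    import arviz as az

    out = {}
    for name, arr in [("a", chains.a), ("b", chains.b),
                      ("sigma2_u0", chains.var_u0), ("sigma2_u1", chains.var_u1),
                      ("sigma2_eps", chains.var_eps)]:
        if arr is None:
            continue
        out[name] = float(az.rhat(az.convert_to_dataset(arr))["x"].values)
    return out
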
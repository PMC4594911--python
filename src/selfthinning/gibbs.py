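"""Gibbs sampler for the hierarchical Bayesian self-thinning models.

Model forms on the (lnN, lnV) plane, with plot clusters indexed by ``i``:

* ``M0`` — pooled line, no random effects (used for conjugate-oracle
  checks and as a fixed-effects baseline)
* ``M1`` — varying intercepts: ``lnV = (a + u0_i) + b lnN + eps``
* ``M2`` — varying slopes: ``lnV = a + (b + u1_i) lnN + eps``
* ``M3`` — both, with independent u0_i and u1_i

All full conditionals are closed-form under the conjugate priors of
:class:`~selfthinning.priors.PriorSpec`:

* ``(a, b)`` jointly bivariate normal given the random effects and the
  precisions (block update — lnN is far from centered, so scalar updates
  would mix poorly);
* each ``u0_i`` / ``u1_i`` univariate normal;
* each precision Gamma(prior shape + count/2, prior rate + sum of
  squares / 2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .priors import PriorSpec, default_priors
from .stand_data import ModelDataset

__all__ = ["ModelForm", "MCMCConfig", "GibbsState", "PosteriorChains",
           "gibbs_sweep", "fit", "ols_line", "precision_conditional"]

log = logging.getLogger(__name__)

#: lower bound applied to sampled variance components; draws below it are
#: floored (and counted) rather than allowed to collapse the conditionals
VARIANCE_FLOOR = 1e-12


class ModelForm(str, Enum):
    """Which cluster-specific deviations the line carries."""

    M0 = "M0"  # pooled (no random effects)
    M1 = "M1"  # varying intercepts
    M2 = "M2"  # varying slopes
    M3 = "M3"  # both, independent

    @property
    def has_u0(self) -> bool:
        return self in (ModelForm.M1, ModelForm.M3)

    @property
    def has_u1(self) -> bool:
        return self in (ModelForm.M2, ModelForm.M3)


@dataclass(frozen=True)
class MCMCConfig:
    """Chain-length settings.

    Defaults mirror a long production run (250,000 iterations, 50,000
    burn-in, thinning 3, 3 chains); tests and quick analyses pass a reduced
    configuration.
    """

    n_iter: int = 250_000
    burn_in: int = 50_000
    thin: int = 3
    n_chains: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in < 0 or self.n_iter <= self.burn_in:
            raise ValueError("need n_iter > burn_in >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")

    @property
    def n_draws_per_chain(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin

    def to_dict(self) -> dict:
        return {"n_iter": self.n_iter, "burn_in": self.burn_in,
                "thin": self.thin, "n_chains": self.n_chains, "seed": self.seed}

    @classmethod
    def from_dict(cls, d: dict) -> "MCMCConfig":
        return cls(**d)


@dataclass
class GibbsState:
    """Current parameter values of one chain."""

    a: float
    b: float
    u0: np.ndarray
    u1: np.ndarray
    var_u0: float
    var_u1: float
    var_eps: float
    floor_hits: int = 0

    def check_finite(self) -> None:
        vals = np.concatenate(([self.a, self.b, self.var_u0, self.var_u1, self.var_eps],
                               self.u0, self.u1))
        if not np.all(np.isfinite(vals)):
            raise FloatingPointError("non-finite Gibbs state")


@dataclass(frozen=True)
class PosteriorChains:
    """Post-burn-in, thinned draws, one row block per chain.

    Scalar parameters have shape ``(n_chains, n_draws)``; random-effect
    vectors have shape ``(n_chains, n_draws, n_plots)`` and are identically
    zero for forms without the component.  ``var_u0``/``var_u1`` are
    ``None`` for forms without the corresponding component.
    """

    form: ModelForm
    a: np.ndarray
    b: np.ndarray
    u0: np.ndarray
    u1: np.ndarray
    var_u0: np.ndarray | None
    var_u1: np.ndarray | None
    var_eps: np.ndarray
    plot_ids: tuple[str, ...]
    floor_hits: int = 0

    @property
    def n_chains(self) -> int:
        return self.a.shape[0]

    @property
    def n_draws(self) -> int:
        return self.a.shape[0] * self.a.shape[1]

    def pooled(self, name: str) -> np.ndarray:
        """Draws of a scalar parameter pooled across chains."""
        arr = getattr(self, name)
        if arr is None:
            raise KeyError(f"model form {self.form.value} has no parameter {name}")
        return np.asarray(arr).reshape(-1) if arr.ndim == 2 else arr.reshape(-1, arr.shape[-1])

    def parameters(self) -> dict[str, np.ndarray]:
        """Pooled draws of every scalar parameter, in report order."""
        out = {"a": self.pooled("a"), "b": self.pooled("b")}
        if self.var_u0 is not None:
            out["sigma2_u0"] = self.pooled("var_u0")
        if self.var_u1 is not None:
            out["sigma2_u1"] = self.pooled("var_u1")
        out["sigma2_eps"] = self.pooled("var_eps")
        return out

    def to_frame(self):
        """Long-format chain export: chain, draw, parameter, value."""
        import pandas as pd

        rows = []
        for name, arr in [("a", self.a), ("b", self.b),
                          ("sigma2_u0", self.var_u0), ("sigma2_u1", self.var_u1),
                          ("sigma2_eps", self.var_eps)]:
            if arr is None:
                continue
            for c in range(arr.shape[0]):
                rows.append(pd.DataFrame({
                    "chain": c + 1,
                    "draw": np.arange(arr.shape[1]) + 1,
                    "parameter": name,
                    "value": arr[c],
                }))
        for uname, uarr, flag in [("u0", self.u0, self.form.has_u0),
                                  ("u1", self.u1, self.form.has_u1)]:
            if not flag:
                continue
            for k, pid in enumerate(self.plot_ids):
                for c in range(uarr.shape[0]):
                    rows.append(pd.DataFrame({
                        "chain": c + 1,
                        "draw": np.arange(uarr.shape[1]) + 1,
                        "parameter": f"{uname}[{pid}]",
                        "value": uarr[c, :, k],
                    }))
        return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------

def precision_conditional(prior_shape: float, prior_rate: float,
                          count: float, sum_sq: float) -> tuple[float, float]:
    """Gamma full-conditional of a precision: (shape + count/2, rate + SS/2)."""
    return prior_shape + count / 2.0, prior_rate + sum_sq / 2.0


def ols_line(dataset: ModelDataset) -> tuple[float, float, float, np.ndarray]:
    """Ordinary least squares of lnV on lnN.

    Returns ``(a_hat, b_hat, s2, cov)`` where ``s2`` is the residual
    variance (n-2 divisor) and ``cov`` the 2x2 coefficient covariance.
    """
    X = np.column_stack([np.ones(dataset.n_obs), dataset.lnN])
    coef, res, *_ = np.linalg.lstsq(X, dataset.lnV, rcond=None)
    resid = dataset.lnV - X @ coef
    dof = max(dataset.n_obs - 2, 1)
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    return float(coef[0]), float(coef[1]), s2, cov


def _sort_canonical(dataset: ModelDataset) -> ModelDataset:
    """Canonical internal order: by plot index, then lnN descending
    (age order — density falls with age), then lnV.  Makes chains invariant
    to the record order of the input."""
    order = np.lexsort((dataset.lnV, -dataset.lnN, dataset.plot_index))
    return ModelDataset(
        lnN=dataset.lnN[order], lnV=dataset.lnV[order],
        plot_index=dataset.plot_index[order], plot_ids=dataset.plot_ids,
    )


def gibbs_sweep(
    state: GibbsState,
    dataset: ModelDataset,
    priors: PriorSpec,
    form: ModelForm,
    rng: np.random.Generator,
    *,
    fixed_var_eps: float | None = None,
) -> GibbsState:
    """One full Gibbs sweep over all blocks; mutates and returns ``state``.

    ``fixed_var_eps`` holds the residual variance at a known value (its
    precision update is skipped) — used for closed-form oracle comparisons.
    """
    state.check_finite()
    y, x, g = dataset.lnV, dataset.lnN, dataset.plot_index - 1
    n = dataset.n_obs
    n_plots = dataset.n_plots
    s2 = state.var_eps

    # --- (a, b) joint bivariate-normal conditional ---
    z = y - state.u0[g] - state.u1[g] * x
    Sx, Sxx = float(x.sum()), float(x @ x)
    XtX = np.array([[n, Sx], [Sx, Sxx]])
    Xtz = np.array([float(z.sum()), float(x @ z)])
    prior_prec = np.diag([
        0.0 if np.isinf(priors.a_var) else 1.0 / priors.a_var,
        0.0 if np.isinf(priors.b_var) else 1.0 / priors.b_var,
    ])
    prior_term = np.array([
        0.0 if np.isinf(priors.a_var) else priors.a_mean / priors.a_var,
        0.0 if np.isinf(priors.b_var) else priors.b_mean / priors.b_var,
    ])
    prec = XtX / s2 + prior_prec
    cov = np.linalg.inv(prec)
    mean = cov @ (Xtz / s2 + prior_term)
    L = np.linalg.cholesky(cov)
    draw = mean + L @ rng.standard_normal(2)
    state.a, state.b = float(draw[0]), float(draw[1])

    counts = np.bincount(g, minlength=n_plots).astype(float)

    # --- u0_i conditionals ---
    if form.has_u0:
        r = y - state.a - (state.b + state.u1[g]) * x
        s_i = np.bincount(g, weights=r, minlength=n_plots)
        prec_i = counts / s2 + 1.0 / state.var_u0
        mean_i = (s_i / s2) / prec_i
        state.u0 = mean_i + rng.standard_normal(n_plots) / np.sqrt(prec_i)

    # --- u1_i conditionals ---
    if form.has_u1:
        r = y - (state.a + state.u0[g]) - state.b * x
        sx_i = np.bincount(g, weights=x * r, minlength=n_plots)
        sxx_i = np.bincount(g, weights=x * x, minlength=n_plots)
        prec_i = sxx_i / s2 + 1.0 / state.var_u1
        mean_i = (sx_i / s2) / prec_i
        state.u1 = mean_i + rng.standard_normal(n_plots) / np.sqrt(prec_i)

    # --- precision conditionals: Gamma(shape + count/2, rate + SS/2) ---
    def _draw_var(shape0: float, rate0: float, count: float, ss: float) -> float:
        shape, rate = precision_conditional(shape0, rate0, count, ss)
        prec = rng.gamma(shape, 1.0 / rate)
        var = 1.0 / prec
        if var < VARIANCE_FLOOR:
            state.floor_hits += 1
            log.info("variance draw %.3e floored at %.0e", var, VARIANCE_FLOOR)
            var = VARIANCE_FLOOR
        return var

    if form.has_u0:
        state.var_u0 = _draw_var(priors.u0_prec_shape, priors.u0_prec_rate,
                                 n_plots, float(state.u0 @ state.u0))
    if form.has_u1:
        state.var_u1 = _draw_var(priors.u1_prec_shape, priors.u1_prec_rate,
                                 n_plots, float(state.u1 @ state.u1))
    if fixed_var_eps is None:
        resid = y - state.a - state.u0[g] - (state.b + state.u1[g]) * x
        state.var_eps = _draw_var(priors.eps_prec_shape, priors.eps_prec_rate,
                                  n, float(resid @ resid))
    else:
        state.var_eps = fixed_var_eps
    return state


def _initial_state(
    dataset: ModelDataset, form: ModelForm, chain: int,
    rng: np.random.Generator, fixed_var_eps: float | None,
) -> GibbsState:
    """Chain 0 starts at the OLS fit; later chains at OLS +/- k*SE."""
    a0, b0, s2, cov = ols_line(dataset)
    if chain > 0:
        k = rng.uniform(1.0, 3.0, size=2) * rng.choice([-1.0, 1.0], size=2)
        a0 += k[0] * np.sqrt(cov[0, 0])
        b0 += k[1] * np.sqrt(cov[1, 1])
    n_plots = dataset.n_plots
    return GibbsState(
        a=a0, b=b0,
        u0=np.zeros(n_plots), u1=np.zeros(n_plots),
        var_u0=0.01 if form.has_u0 else 0.0,
        var_u1=0.01 if form.has_u1 else 0.0,
        var_eps=fixed_var_eps if fixed_var_eps is not None else max(s2, 1e-6),
    )


def fit(
    dataset: ModelDataset,
    form: ModelForm | str = ModelForm.M1,
    priors: PriorSpec | None = None,
    mcmc: MCMCConfig | None = None,
    *,
    fixed_var_eps: float | None = None,
) -> PosteriorChains:
    """Fit one model form by Gibbs sampling.

    Runs ``mcmc.n_chains`` independent chains from dispersed initial
    values, discards the burn-in, thins, and returns the stacked draws.
    Deterministic given ``mcmc.seed`` and the dataset contents (records are
    sorted canonically first, so the input order is irrelevant).

    Raises
    ------
    ValueError
        If a random-effects form is requested on a single-plot dataset.
    """
    form = ModelForm(form)
    priors = priors if priors is not None else default_priors()
    mcmc = mcmc if mcmc is not None else MCMCConfig()
    if dataset.n_obs == 0:
        raise ValueError("empty dataset")
    if (form.has_u0 or form.has_u1) and dataset.n_plots < 2:
        raise ValueError(
            f"model form {form.value} needs >= 2 plots for its random effects; "
            f"got {dataset.n_plots}"
        )
    ds = _sort_canonical(dataset)
    n_draws = mcmc.n_draws_per_chain
    n_plots = ds.n_plots

    a = np.empty((mcmc.n_chains, n_draws))
    b = np.empty_like(a)
    u0 = np.zeros((mcmc.n_chains, n_draws, n_plots))
    u1 = np.zeros_like(u0)
    v0 = np.empty_like(a) if form.has_u0 else None
    v1 = np.empty_like(a) if form.has_u1 else None
    ve = np.empty_like(a)
    floor_hits = 0

    root = np.random.SeedSequence(mcmc.seed)
    for c, ss in enumerate(root.spawn(mcmc.n_chains)):
        rng = np.random.default_rng(ss)
        state = _initial_state(ds, form, c, rng, fixed_var_eps)
        kept = 0
        for it in range(mcmc.n_iter):
            gibbs_sweep(state, ds, priors, form, rng, fixed_var_eps=fixed_var_eps)
            if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0 and kept < n_draws:
                a[c, kept], b[c, kept] = state.a, state.b
                u0[c, kept] = state.u0
                u1[c, kept] = state.u1
                if v0 is not None:
                    v0[c, kept] = state.var_u0
                if v1 is not None:
                    v1[c, kept] = state.var_u1
                ve[c, kept] = state.var_eps
                kept += 1
        floor_hits += state.floor_hits

    return PosteriorChains(
        form=form, a=a, b=b, u0=u0, u1=u1,
        var_u0=v0, var_u1=v1, var_eps=ve,
        plot_ids=ds.plot_ids, floor_hits=floor_hits,
    )
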
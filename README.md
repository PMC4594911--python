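# selfthinning

Hierarchical Bayesian estimation of the self-thinning line for even-aged
forest stands, with a stochastic-frontier comparator and a synthetic
stand-panel generator.

## The problem

In fully stocked even-aged stands, competition kills trees as the
survivors grow, and mean tree size tracks an upper boundary in density —
the self-thinning line. On log–log axes it is linear,

    lnV = a + b lnN,

with `V` mean stem volume (dm³/tree), `N` surviving density (trees/ha),
and slope `b` classically near −3/2. Estimating `(a, b)` from permanent
plots is complicated by the data's hierarchy: each plot contributes a
whole trajectory of repeated measurements, and plots differ in spacing and
site. This package is for forest biometricians who want the line with
honest uncertainty: it fits plot-level random-effects forms

    M1: lnV = (a + u0_i) + b lnN + ε          u0_i ~ N(0, σ₀²)
    M2: lnV = a + (b + u1_i) lnN + ε          u1_i ~ N(0, σ₁²)
    M3: lnV = (a + u0_i) + (b + u1_i) lnN + ε

by a conjugate Gibbs sampler with an informative slope prior
`b ~ N(−1.52, 0.39)` elicited from published slope estimates, compares
forms by DIC and RMSE, partitions variance into between- and within-plot
shares, and fits the classical normal–half-normal stochastic frontier
(`lnV = a + b lnN + v − u`, `u ≥ 0`) as the main competing estimator of
the upper boundary. Plots enter the analysis only once their cumulative
mortality exceeds 10% — before that they are not yet self-thinning.

Because suitable long-term spacing-trial data are rarely shareable, a
calibrated synthetic generator (`selfthinning.synthetic`) produces panels
with the assumed hierarchical structure for testing and simulation
studies. See `docs/methods.md` for the full model account.

## Worked example

```python
import selfthinning as st

panel = st.generate_table1_like(seed=7)        # 15-plot synthetic spacing trial
kept = st.filter_self_thinning(panel)          # mortality > 10%
print(f"{kept.n_plots} of {panel.n_plots} plots self-thinning")

ds = st.to_log_pairs(kept)
mcmc = st.MCMCConfig(n_iter=20_000, burn_in=4_000, thin=3, n_chains=3, seed=7)
chains = st.fit(ds, "M1", mcmc=mcmc)

print(st.summarize(chains).table.round(3))
dbar, dhat, p_d, dic = st.dic(chains, ds)
print(f"DIC = {dic:.1f} (pD = {p_d:.2f}),  RMSE = {st.rmse(chains, ds):.4f}")
between, within = st.variance_partition(chains)
print(f"between-plot share = {between:.2f}%, within = {within:.2f}%")

sff = st.fit_sff(ds)
print(f"SFF: a = {sff.intercept_a:.2f} (SE {sff.se_a:.2f}), "
      f"b = {sff.slope_b:.2f} (SE {sff.se_b:.2f}), RMSE = {sff.rmse:.4f}")
```

prints

```
10 of 15 plots self-thinning
              mean     sd  median   lower  higher
a           17.182  0.765  17.178  15.685  18.688
b           -1.523  0.092  -1.523  -1.705  -1.343
sigma2_u0    0.002  0.002   0.001   0.000   0.007
sigma2_eps   0.015  0.003   0.015   0.010   0.022
DIC = -76.2 (pD = 6.14),  RMSE = 0.1162
between-plot share = 9.94%, within = 90.06%
SFF: a = 17.17 (SE 0.60), b = -1.52 (SE 0.07), RMSE = 0.1207
```

Reading this: the posterior slope −1.52 ± 0.09 is consistent with the
−3/2 rule (the panel was generated at b = −1.5); the between-plot
intercept variance σ₀² is an order of magnitude below the residual σ², so
only ~10% of the variation is between plots — planting density barely
moves the line. The hierarchical fit's RMSE (0.116) edges out the frontier
comparator's (0.121). On this realization the frontier's one-sided
component is not supported by the likelihood, so `fit_sff` warns and
returns its OLS-equivalent fit.

The same pipeline runs from the shell:

```
selfthinning simulate --outdir out --seed 7
selfthinning fit --config run.yaml --sff
selfthinning compare --config run.yaml
```

Field data go in as CSV with columns
`plot_id, planting_density, age, density, mean_volume`
(`read_stand_table` accepts a column-name dialect map for other headers).

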
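"""Posterior summaries, DIC, RMSE and variance partition."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

import selfthinning as st
from selfthinning.evaluate import rmse_from_residuals, variance_partition_from_medians
from selfthinning.gibbs import PosteriorChains

from conftest import make_dataset


def chains_from_draws(a, b, var_eps, u0=None, u1=None, var_u0=None, var_u1=None,
                      form=st.ModelForm.M0, plot_ids=("P1",)):
    """Build a PosteriorChains object from explicit draws (one chain)."""
    a = np.asarray(a, float)[None, :]
    m = a.shape[1]
    k = len(plot_ids)
    z = np.zeros((1, m, k))
    return PosteriorChains(
        form=form, a=a, b=np.asarray(b, float)[None, :],
        u0=z if u0 is None else np.asarray(u0, float)[None, :, :],
        u1=z if u1 is None else np.asarray(u1, float)[None, :, :],
        var_u0=None if var_u0 is None else np.asarray(var_u0, float)[None, :],
        var_u1=None if var_u1 is None else np.asarray(var_u1, float)[None, :],
        var_eps=np.asarray(var_eps, float)[None, :],
        plot_ids=tuple(plot_ids),
    )


class TestSummarize:
    def test_constant_chain(self):
        ch = chains_from_draws([2.0] * 50, [-1.5] * 50, [0.1] * 50)
        row = st.summarize(ch).table.loc["a"]
        assert row["mean"] == row["median"] == 2.0
        assert row["sd"] == 0.0
        assert row["lower"] == row["higher"] == 2.0

    def test_order_statistic_median(self):
        vals = np.arange(1.0, 101.0)
        ch = chains_from_draws(vals, vals, np.ones(100))
        assert st.summarize(ch).table.loc["a", "median"] == pytest.approx(50.5)

    def test_symmetric_chain_mean_matches_median(self):
        vals = np.random.default_rng(0).normal(3.0, 1.0, 20001)
        ch = chains_from_draws(vals, vals, np.ones(len(vals)))
        row = st.summarize(ch).table.loc["a"]
        assert row["mean"] == pytest.approx(row["median"], abs=0.05)

    def test_quantiles_ordered(self, thinning_dataset, quick_mcmc):
        ch = st.fit(thinning_dataset, "M1", mcmc=quick_mcmc)
        tab = st.summarize(ch, include_random_effects=True).table
        assert (tab["lower"] <= tab["median"]).all()
        assert (tab["median"] <= tab["higher"]).all()


class TestDIC:
    def test_degenerate_chain_has_zero_pd(self):
        ds = make_dataset([8.0, 8.2, 8.4], [5.0, 4.7, 4.4])
        ch = chains_from_draws([17.0] * 10, [-1.5] * 10, [0.02] * 10)
        dbar, dhat, p_d, dic_val = st.dic(ch, ds)
        assert p_d == pytest.approx(0.0, abs=1e-10)
        assert dic_val == pytest.approx(dbar, abs=1e-10)

    def test_two_draw_hand_arithmetic(self):
        # hand-computed through the normal log-density on 3 points
        x = np.array([8.0, 8.2, 8.4])
        y = np.array([5.0, 4.7, 4.4])
        ds = make_dataset(x, y)
        draws = [(17.0, -1.5, 0.02), (16.5, -1.45, 0.03)]
        devs = []
        for a, b, s2 in draws:
            r = y - a - b * x
            ll = np.sum(-0.5 * np.log(2 * np.pi * s2) - r**2 / (2 * s2))
            devs.append(-2 * ll)
        dbar_exp = np.mean(devs)
        a_bar, b_bar, s2_bar = 16.75, -1.475, 0.025
        r = y - a_bar - b_bar * x
        dhat_exp = -2 * np.sum(-0.5 * np.log(2 * np.pi * s2_bar) - r**2 / (2 * s2_bar))
        ch = chains_from_draws([17.0, 16.5], [-1.5, -1.45], [0.02, 0.03])
        dbar, dhat, p_d, dic_val = st.dic(ch, ds)
        assert dbar == pytest.approx(dbar_exp, abs=1e-10)
        assert dhat == pytest.approx(dhat_exp, abs=1e-10)
        assert dic_val == pytest.approx(dbar_exp + (dbar_exp - dhat_exp), abs=1e-10)

    def test_effective_parameters_near_three_for_pooled_line(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(7.5, 9.0, 500)
        y = 17.0 - 1.5 * x + rng.normal(0, 0.15, 500)
        ds = make_dataset(x, y)
        ch = st.fit(ds, "M0", priors=st.default_priors().flat_coefficients(),
                    mcmc=st.MCMCConfig(n_iter=6000, burn_in=1000, thin=1,
                                       n_chains=2, seed=3))
        _, _, p_d, _ = st.dic(ch, ds)
        assert p_d == pytest.approx(3.0, abs=0.6)

    def test_dic_prefers_generative_form(self, reseeded):
        votes = 0
        for r in range(5):
            cfg = st.SimConfig(seed=300 + r, sd_u0=0.3, n_plots=12)
            ds = st.to_log_pairs(st.generate_panel(cfg))
            mc = reseeded(r)
            dic_m1 = st.dic(st.fit(ds, "M1", mcmc=mc), ds)[3]
            dic_m0 = st.dic(st.fit(ds, "M0", mcmc=mc), ds)[3]
            votes += dic_m1 < dic_m0
        assert votes >= 3


class TestRMSE:
    def test_n_minus_one_divisor(self):
        assert rmse_from_residuals([1.0, -1.0]) == pytest.approx(np.sqrt(2.0))

    def test_perfect_predictions(self):
        x = np.array([8.0, 8.2, 8.4])
        y = 17.0 - 1.5 * x
        ds = make_dataset(x, y)
        ch = chains_from_draws([17.0] * 5, [-1.5] * 5, [0.01] * 5)
        assert st.rmse(ch, ds) == pytest.approx(0.0, abs=1e-12)

    def test_single_residual_rejected(self):
        with pytest.raises(ValueError, match="n-1"):
            rmse_from_residuals([1.0])

    def test_invariant_under_reordering(self, thinning_dataset, quick_mcmc):
        ch = st.fit(thinning_dataset, "M1", mcmc=quick_mcmc)
        perm = np.random.default_rng(3).permutation(thinning_dataset.n_obs)
        shuffled = st.ModelDataset(
            lnN=thinning_dataset.lnN[perm], lnV=thinning_dataset.lnV[perm],
            plot_index=thinning_dataset.plot_index[perm],
            plot_ids=thinning_dataset.plot_ids)
        assert st.rmse(ch, shuffled) == pytest.approx(st.rmse(ch, thinning_dataset))

    def test_conditional_not_worse_than_marginal_with_plot_effects(self, reseeded):
        cfg = st.SimConfig(seed=77, sd_u0=0.2)
        ds = st.to_log_pairs(st.generate_panel(cfg))
        ch = st.fit(ds, "M1", mcmc=reseeded(7))
        assert st.rmse(ch, ds, "conditional") <= st.rmse(ch, ds, "marginal")


class TestVariancePartition:
    def test_reported_medians_worked_example(self):
        between, within = variance_partition_from_medians(0.009, 0.031)
        assert between == pytest.approx(29.03, abs=0.005)
        assert within == pytest.approx(70.97, abs=0.005)

    def test_zero_between(self):
        assert variance_partition_from_medians(0.0, 0.03) == (0.0, 100.0)

    def test_equal_components_split_evenly(self):
        ch = chains_from_draws([17.0] * 9, [-1.5] * 9, [0.02] * 9,
                               var_u0=[0.02] * 9, form=st.ModelForm.M1)
        assert st.variance_partition(ch, total="sum") == (50.0, 50.0)

    def test_fixed_effects_chains_rejected(self):
        ch = chains_from_draws([17.0] * 5, [-1.5] * 5, [0.02] * 5)
        with pytest.raises(ValueError, match="random-effects"):
            st.variance_partition(ch)

    @given(between=hst.floats(0.0, 0.05), resid=hst.floats(0.01, 0.10))
    @settings(max_examples=50, deadline=None)
    def test_shares_sum_to_exactly_100(self, between, resid):
        b, w = variance_partition_from_medians(min(between, resid), resid)
        assert b + w == 100.0
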
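"""Recruitment-model likelihood, quadrature and fitting tests."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import seedlim as sl
from seedlim.recruitment import (
    FitOptions,
    Model,
    _PlotData,
    compare_models,
    nb_log_pmf,
)

from helpers import dense_grid_marginal_loglik, single_species_design, \
    tiny_records


class TestBhMean:
    @pytest.mark.parametrize("S, P0, Rmax, expected", [
        (1000, 0.01, 5, 10 / 3),
        (0, 0.5, 5, 0.0),
        (1e9, 0.01, 5, 5.0),
    ])
    def test_examples(self, S, P0, Rmax, expected):
        assert sl.bh_mean(S, P0, Rmax) == pytest.approx(expected, rel=1e-6)

    def test_infinite_rmax_is_linear(self):
        assert sl.bh_mean(123.0, 0.02, math.inf) == pytest.approx(2.46)

    def test_negative_seed_input_rejected(self):
        with pytest.raises(ValueError):
            sl.bh_mean(-1.0, 0.1, 5.0)

    @given(P0=st.floats(0.001, 1.0), Rmax=st.floats(0.1, 100.0))
    @settings(max_examples=100, derandomize=True)
    def test_increasing_concave_and_bounded(self, P0, Rmax):
        S = np.linspace(0.0, 10 * Rmax / P0, 200)
        R = sl.bh_mean(S, P0, Rmax)
        assert (np.diff(R) > 0).all()            # strictly increasing
        assert (np.diff(R, 2) < 1e-9).all()      # concave
        assert (R <= np.minimum(P0 * S, Rmax) + 1e-12).all()

    @given(P0=st.floats(0.001, 1.0), Rmax=st.floats(0.1, 100.0))
    @settings(max_examples=50, derandomize=True)
    def test_per_seed_mean_strictly_decreasing(self, P0, Rmax):
        S = np.linspace(1.0, 10 * Rmax / P0, 100)
        per_seed = sl.bh_mean(S, P0, Rmax) / S
        assert (np.diff(per_seed) < 0).all()


class TestNbLogPmf:
    def test_geometric_case(self):
        assert sl.nb_log_pmf(0, 1, 1) == pytest.approx(math.log(0.5))

    def test_poisson_limit(self):
        expected = stats.poisson.logpmf(2, 2)
        assert sl.nb_log_pmf(2, 2, 1e6) == pytest.approx(expected, abs=1e-4)

    def test_matches_scipy_nbinom(self):
        y = np.arange(0, 30)
        mu, k = 3.7, 1.4
        expected = stats.nbinom.logpmf(y, k, k / (k + mu))
        np.testing.assert_allclose(sl.nb_log_pmf(y, mu, k), expected,
                                   rtol=1e-10)

    def test_normalization(self):
        y = np.arange(0, 3000)
        total = np.exp(sl.nb_log_pmf(y, 5.0, 0.5)).sum()
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_impossible_observation_returns_neg_inf(self):
        assert sl.nb_log_pmf(3, 0.0, 1.0) == -math.inf
        assert sl.nb_log_pmf(0, 0.0, 1.0) == 0.0


class TestMarginalLoglik:
    def test_sigma_zero_equals_fixed_effects_sum(self):
        df = tiny_records()
        params = sl.BHParams(P0=0.05, Rmax=3.0, k=1.5, sigma_plot=0.0)
        ll = sl.marginal_loglik(df, params, "DD", n_nodes=20)
        data = _PlotData.from_records(df, 3)
        m = 0.05 * data.S / (1 + 0.05 * data.S / 3.0)
        direct = float(nb_log_pmf(data.y[data.mask], m[data.mask], 1.5).sum())
        assert ll == pytest.approx(direct, abs=1e-12)

    def test_matches_dense_grid_oracle(self):
        df = tiny_records(seed=3)
        params = sl.BHParams(P0=0.05, Rmax=3.0, k=1.5, sigma_plot=0.7)
        ll = sl.marginal_loglik(df, params, "DD", n_nodes=20)
        oracle = dense_grid_marginal_loglik(df, params, "DD")
        assert ll == pytest.approx(oracle, abs=1e-6)

    def test_node_doubling_self_consistency(self):
        df = tiny_records(seed=5)
        params = sl.BHParams(P0=0.02, Rmax=2.0, k=0.8, sigma_plot=1.2)
        ll20 = sl.marginal_loglik(df, params, "DD", n_nodes=20)
        ll40 = sl.marginal_loglik(df, params, "DD", n_nodes=40)
        assert abs(ll20 - ll40) < 1e-6

    def test_invariant_to_row_order_and_plot_labels(self):
        df = tiny_records(seed=7)
        params = sl.BHParams(P0=0.05, Rmax=3.0, k=1.5, sigma_plot=0.5)
        base = sl.marginal_loglik(df, params, "DD")
        shuffled = df.sample(frac=1, random_state=0)
        assert sl.marginal_loglik(shuffled, params, "DD") \
            == pytest.approx(base, abs=1e-10)
        relabeled = df.copy()
        relabeled["plot_id"] = relabeled["plot_id"].map(
            {"P0": "Zebra", "P1": "Alpha", "P2": "Mid"})
        assert sl.marginal_loglik(relabeled, params, "DD") \
            == pytest.approx(base, abs=1e-10)

    def test_too_few_nodes_rejected(self):
        df = tiny_records()
        with pytest.raises(ValueError):
            sl.marginal_loglik(df, sl.BHParams(P0=0.1, Rmax=1, k=1), "DD",
                               n_nodes=3)


@pytest.fixture(scope="module")
def dd_dataset():
    truth = sl.TrueParams(P0=0.02, Rmax=6.0, k=2.0, sigma_plot=0.0)
    design = single_species_design(n_plots=10, stations_per_plot=8)
    return sl.simulate_experiment(design, truth, 2024), truth


class TestFitModel:

    def test_fit_beats_coarse_grid_oracle(self, dd_dataset):
        df, _ = dd_dataset
        opts = FitOptions(n_nodes=12, n_starts=3)
        fit = sl.fit_model(df, 3, "DD", opts)
        data = _PlotData.from_records(df, 3)
        S, y = data.S[data.mask], data.y[data.mask]
        best = -np.inf
        for P0 in np.geomspace(5e-4, 0.5, 25):
            for Rmax in np.geomspace(0.2, 60, 25):
                m = P0 * S / (1 + P0 * S / Rmax)
                for k in np.geomspace(0.1, 100, 12):
                    ll = float(nb_log_pmf(y, m, k).sum())
                    if ll > best:
                        best = ll
        assert fit.loglik >= best - 0.01

    def test_wald_intervals_bracket_estimates(self, dd_dataset):
        df, truth = dd_dataset
        fit = sl.fit_model(df, 3, "DD", FitOptions(n_nodes=12, n_starts=3))
        lo, hi = fit.ci["P0"]
        assert lo <= fit.estimates.P0 <= hi

    def test_aic_counts_free_parameters(self, dd_dataset):
        df, _ = dd_dataset
        opts = FitOptions(n_nodes=8, n_starts=2)
        for model, n_free in [("DD", 4), ("DI", 3), ("NO_DI", 3),
                              ("SEED_ONLY", 2)]:
            fit = sl.fit_model(df, 3, model, opts)
            assert fit.aic == pytest.approx(2 * n_free - 2 * fit.loglik)

    def test_all_zero_counts_flagged(self):
        df = tiny_records(seed=11)
        df["seedling_count"] = 0
        with pytest.warns(UserWarning, match="zero"):
            fit = sl.fit_model(df, 3, "DD", FitOptions(n_nodes=8, n_starts=2))
        assert fit.boundary

    def test_single_seed_level_rejected_for_saturating_model(self):
        df = tiny_records(seed=13)
        df["seeds_added"] = 50
        with pytest.raises(ValueError, match="distinct"):
            sl.fit_model(df, 3, "DD")


class TestCompareModels:
    def _fake(self, model, loglik, n_obs=100):
        est = sl.BHParams(P0=0.01, Rmax=5.0, k=1.0)
        model = Model(model)
        aic = 2 * model.n_free_params - 2 * loglik
        return sl.FitResult(model=model, estimates=est, ci={},
                            loglik=loglik, aic=aic, n_obs=n_obs,
                            converged=True, n_quadrature_nodes=8)

    def test_aic_arithmetic_and_selection(self):
        table = compare_models([self._fake("DD", -100), self._fake("DI", -105)])
        assert list(table.aic) == [208.0, 216.0]
        assert table.model.iloc[0] == "DD"
        assert bool(table.selected.iloc[0])
        assert bool(table.distinguished.iloc[0])

    def test_equal_aic_tie_flagged_with_canonical_order(self):
        # DI has one fewer parameter: equal AIC needs loglik offset 1
        table = compare_models([self._fake("DI", -101), self._fake("DD", -100)])
        assert table.aic.iloc[0] == table.aic.iloc[1]
        assert table.model.iloc[0] == "DD"  # canonical enum order breaks tie
        assert bool(table.tie.iloc[0])
        assert not bool(table.distinguished.iloc[0])

    def test_single_fit_selected_not_distinguished(self):
        table = compare_models([self._fake("DD", -50)])
        assert bool(table.selected.iloc[0])
        assert not bool(table.distinguished.iloc[0])

    def test_mismatched_observations_rejected(self):
        with pytest.raises(ValueError, match="n_obs"):
            compare_models([self._fake("DD", -100, 100),
                            self._fake("DI", -90, 90)])
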
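"""Limitation decomposition algebra, crossovers and trends."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import seedlim as sl
from seedlim.limitation import DecompositionUndefinedError


def params(P0=0.01, Rmax=5.0, k=1.0, S_amb=0.0):
    return sl.BHParams(P0=P0, Rmax=Rmax, k=k, S_amb=S_amb)


class TestLimitationAt:
    def test_worked_example(self):
        L_S, L_DI, L_DD, L_E = sl.limitation_at(100, params())
        assert L_S == pytest.approx(4.1667, abs=1e-4)
        assert L_DI == pytest.approx(3.9286, abs=1e-4)
        assert L_DD == pytest.approx(0.1667, abs=1e-4)
        assert L_E == pytest.approx(99.1667, abs=1e-4)

    def test_no_seeds_only_seed_limitation(self):
        L_S, L_DI, L_DD, L_E = sl.limitation_at(0, params())
        assert L_S == pytest.approx(5.0)
        assert (L_DI, L_DD, L_E) == (0.0, 0.0, 0.0)

    def test_p0_one_removes_density_independent_loss(self):
        for S in (0.5, 10, 1000):
            _, L_DI, _, _ = sl.limitation_at(S, params(P0=1.0))
            assert L_DI == pytest.approx(0.0, abs=1e-12)

    def test_infinite_rmax_undefined(self):
        with pytest.raises(DecompositionUndefinedError):
            sl.limitation_at(10, sl.BHParams(P0=0.1, Rmax=math.inf, k=1.0))

    @given(P0=st.floats(0.001, 1.0), Rmax=st.floats(0.1, 50.0),
           S=st.floats(0.01, 1e5))
    @settings(max_examples=200, derandomize=True)
    def test_ordering_invariants(self, P0, Rmax, S):
        L_S, L_DI, L_DD, L_E = sl.limitation_at(S, params(P0=P0, Rmax=Rmax))
        assert min(L_S, L_DI, L_DD, L_E) >= -1e-9
        assert L_E >= max(L_DI, L_DD) - 1e-9
        assert L_DI + L_DD <= L_E + 1e-9


class TestCrossovers:
    def test_seed_establishment_closed_form_is_rmax(self):
        assert sl.crossover_seed_establishment(params(Rmax=4.5)) == 4.5

    def test_ambient_multiple_conversion(self):
        p = params(Rmax=4.5, S_amb=0.9)
        curve = sl.limitation_curve(p)
        assert curve.crossovers_dict()["seed_vs_establishment_multiple"] \
            == pytest.approx(5.0)

    @pytest.mark.parametrize("P0, Rmax, expected", [
        (0.01, 4.0, 396.0),
        (0.5, 10.0, 10.0),
        (1.0, 5.0, 0.0),
    ])
    def test_dd_di_closed_form(self, P0, Rmax, expected):
        assert sl.crossover_dd_di(params(P0=P0, Rmax=Rmax)) \
            == pytest.approx(expected)

    @given(P0=st.floats(0.001, 0.999), Rmax=st.floats(0.1, 50.0))
    @settings(max_examples=200, derandomize=True)
    def test_numeric_roots_match_algebra(self, P0, Rmax):
        p = params(P0=P0, Rmax=Rmax)
        s1 = sl.crossover_seed_establishment(p, numeric=True)
        assert abs(s1 - Rmax) / Rmax < 1e-6
        s2 = sl.crossover_dd_di(p, numeric=True)
        closed = Rmax * (1 - P0) / P0
        assert abs(s2 - closed) / closed < 1e-6


class TestLimitationCurve:
    def test_grid_at_rmax_equates_seed_and_establishment(self):
        p = params(Rmax=3.3)
        curve = sl.limitation_curve(p, grid=np.array([3.3]))
        assert curve.L_S[0] == pytest.approx(curve.L_E[0])

    def test_monotonicity_over_default_grid(self):
        curve = sl.limitation_curve(params(S_amb=0.145))
        assert (np.diff(curve.L_S) < 0).all()
        assert (np.diff(curve.L_E) > 0).all()

    def test_rescaling_seeds_and_ambient_preserves_multiples(self):
        p = params(Rmax=2.0)
        c1 = sl.limitation_curve(p, grid=np.array([1.0, 10.0]), ambient=0.5)
        c2 = sl.limitation_curve(p, grid=np.array([2.0, 20.0]), ambient=1.0)
        np.testing.assert_allclose(
            c1.to_frame().ambient_multiple, c2.to_frame().ambient_multiple)

    def test_nonpositive_ambient_omits_conversion(self):
        with pytest.warns(UserWarning, match="ambient"):
            curve = sl.limitation_curve(params(), grid=np.array([1.0, 2.0]),
                                        ambient=0.0)
        assert "ambient_multiple" not in curve.to_frame()
        assert "dd_vs_di_multiple" not in curve.crossovers_dict()

    def test_bad_grid_rejected(self):
        with pytest.raises(ValueError):
            sl.limitation_curve(params(), grid=np.array([2.0, 1.0]))


class TestTemporalTrend:
    def test_perfect_linear_decline(self):
        months = [3, 6, 9, 12, 15, 18]
        values = [10 - 0.5 * m for m in months]
        tr = sl.temporal_trend(values, months)
        assert tr.pearson_r == pytest.approx(-1.0)
        assert tr.p_value < 1e-6
        assert tr.df == 4

    def test_t_statistic_identity(self):
        rng = np.random.default_rng(0)
        months = np.arange(3, 25, 3)
        values = -0.1 * months + rng.normal(0, 1, len(months))
        tr = sl.temporal_trend(values, months)
        expected_t = tr.pearson_r * math.sqrt(
            tr.df / (1 - tr.pearson_r ** 2))
        assert tr.t_stat == pytest.approx(expected_t)

    def test_constant_series_flagged_undefined(self):
        tr = sl.temporal_trend([1.0, 1.0, 1.0], [3, 6, 9])
        assert tr.undefined

    def test_type_one_error_rate_near_nominal(self):
        rng = np.random.default_rng(42)
        months = np.arange(3, 25, 3)
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            tr = sl.temporal_trend(rng.normal(size=len(months)), months)
            hits += tr.p_value < 0.05
        # binomial(1000, 0.05): 3 sigma band around 50
        assert abs(hits - 50) < 3 * math.sqrt(1000 * 0.05 * 0.95)


class TestEffectTimeSlope:
    def _effects(self, slopes_by_species, months=(3, 6, 9, 12), noise=0.0,
                 seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for sp, slope in slopes_by_species.items():
            for m in months:
                for plot in ("P1", "P2", "P3"):
                    rows.append(dict(
                        plot_id=plot, species_code=sp, aug_multiple=25.0,
                        census_month=m,
                        E=0.3 + slope * m + rng.normal(0, noise),
                        n_quadrats=1, flagged=False))
        return pd.DataFrame(rows)

    def test_constant_effects_zero_slope(self):
        out = sl.effect_time_slope(self._effects({"A": 0.0, "B": 0.0}))
        assert out["slope"] == pytest.approx(0.0, abs=1e-12)

    def test_exact_common_decline_recovered(self):
        out = sl.effect_time_slope(self._effects({"A": -0.01, "B": -0.01,
                                                  "C": -0.01}))
        assert out["slope"] == pytest.approx(-0.01, abs=1e-10)

    def test_single_species_falls_back_to_ols(self):
        out = sl.effect_time_slope(self._effects({"A": -0.02}, noise=0.001))
        assert out["method"] == "ols_fallback"
        assert out["slope"] == pytest.approx(-0.02, abs=0.005)

    def test_sign_recovered_under_noise(self):
        hits = 0
        for rep in range(100):
            eff = self._effects({"A": -0.01, "B": -0.01, "C": -0.01,
                                 "D": -0.01, "E": -0.01},
                                noise=0.02, seed=rep)
            out = sl.effect_time_slope(eff)
            hits += out["slope"] < 0
        assert hits >= 95
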
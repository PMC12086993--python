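"""Yield-density model predictions, NLS fitting, and inference columns."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from addseries.models import (
    BicultureCompetition,
    FitError,
    MonocultureYieldDensity,
    coefficient_table,
    fit_biculture,
    fit_monoculture,
    predict_biculture,
    predict_monoculture,
    pseudo_r2,
)


def mono_frame(N, w):
    return pd.DataFrame(
        {"species": "BRTE", "log_biomass": np.log(w), "n_total": N,
         "n_self": N, "n_other": 0.0}
    )


def bi_frame(ns, no, w):
    return pd.DataFrame(
        {"species": "BRTE", "log_biomass": np.log(w), "n_total": ns + no,
         "n_self": ns, "n_other": no}
    )


class TestPredictions:
    def test_no_neighbours_returns_intercept(self):
        assert predict_monoculture(0.25, 3.0, 1.2, 0) == 0.25
        assert predict_biculture(0.25, 1.0, 2.0, 1.2, 0, 0) == 0.25

    def test_simple_hand_values(self):
        assert predict_monoculture(0.1, 1.0, 1.0, 1) == pytest.approx(0.05)
        assert predict_biculture(1.0, 0.0, 1.0, 1.0, 5, 1) == pytest.approx(0.5)

    def test_fitted_magnitude_back_transform(self):
        # independent hand evaluation of 0.113*(1+9.1804*4)^-0.96848
        assert predict_monoculture(0.113, 9.18040, 0.96848, 4) == pytest.approx(
            0.0033588, abs=5e-7
        )
        # biculture counterpart at densities (2, 2)
        assert predict_biculture(
            0.10768, 0.13090, 5.6387, 0.96848, 2, 2
        ) == pytest.approx(0.0093000, abs=5e-7)

    def test_biculture_reduces_to_monoculture_without_other_species(self):
        N = np.arange(0, 20, dtype=float)
        np.testing.assert_allclose(
            predict_biculture(0.2, 0.7, 3.0, 1.1, N, np.zeros_like(N)),
            predict_monoculture(0.2, 0.7, 1.1, N),
        )

    @given(
        wm=st.floats(0.01, 1.0),
        c1=st.floats(0.05, 5.0),
        c2=st.floats(0.05, 5.0),
        b=st.floats(0.2, 2.0),
    )
    @settings(deadline=None, max_examples=50)
    def test_predictions_strictly_decrease_with_density(self, wm, c1, c2, b):
        grid = np.arange(0, 10, dtype=float)
        along_self = predict_biculture(wm, c1, c2, b, grid, 2.0)
        along_other = predict_biculture(wm, c1, c2, b, 2.0, grid)
        assert np.all(np.diff(along_self) < 0)
        assert np.all(np.diff(along_other) < 0)

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            predict_monoculture(0.1, 1.0, 1.0, -1)
        with pytest.raises(ValueError):
            predict_biculture(0.1, 1.0, 1.0, 1.0, -1, 0)


class TestMonocultureFit:
    def test_noise_free_recovery(self):
        N = np.repeat([1.0, 2.0, 4.0, 8.0, 16.0], 4)
        w = predict_monoculture(0.1, 1.0, 1.0, N)
        est = MonocultureYieldDensity().fit(N[:, None], w)
        assert est.wm_ == pytest.approx(0.1, rel=1e-6)
        assert est.a_ == pytest.approx(1.0, rel=1e-6)
        assert est.b_ == pytest.approx(1.0, rel=1e-6)
        assert est.pseudo_r2_ == pytest.approx(1.0, abs=1e-9)

    def test_fit_beats_dense_parameter_grid(self, rng):
        N = np.repeat([1.0, 2.0, 4.0, 8.0, 16.0], 6)
        w = predict_monoculture(0.12, 0.8, 1.1, N) * np.exp(rng.normal(0, 0.3, N.size))
        est = MonocultureYieldDensity().fit(N[:, None], w)
        ly = np.log(w)

        def sse(wm, a, b):
            return np.sum((ly - np.log(predict_monoculture(wm, a, b, N))) ** 2)

        grid = [
            sse(wm, a, b)
            for wm in np.geomspace(0.05, 0.3, 15)
            for a in np.geomspace(0.2, 3.0, 15)
            for b in np.geomspace(0.4, 2.5, 15)
        ]
        assert est.sse_ <= min(grid) + 1e-9

    def test_too_few_density_levels_rejected(self):
        N = np.repeat([2.0, 4.0], 5)
        with pytest.raises(FitError, match="distinct density"):
            MonocultureYieldDensity().fit(N[:, None], np.full(10, 0.1))

    def test_covariance_is_symmetric_psd(self, rng):
        N = np.repeat([1.0, 2.0, 4.0, 8.0, 16.0], 5)
        w = predict_monoculture(0.1, 1.0, 1.0, N) * np.exp(rng.normal(0, 0.2, N.size))
        est = MonocultureYieldDensity().fit(N[:, None], w)
        np.testing.assert_allclose(est.covariance_, est.covariance_.T)
        assert np.all(np.linalg.eigvalsh(est.covariance_) >= 0)

    def test_sklearn_params_round_trip(self):
        est = MonocultureYieldDensity(max_restarts=3)
        assert MonocultureYieldDensity(**est.get_params()).max_restarts == 3


class TestBicultureFit:
    def test_noise_free_recovery_with_fixed_exponent(self):
        ns = np.tile(np.repeat([2.0, 4.0, 8.0], 3), 3)
        no = np.repeat([2.0, 4.0, 8.0], 9)
        w = predict_biculture(0.11, 0.13, 5.6, 0.97, ns, no)
        est = BicultureCompetition(b=0.97).fit(np.c_[ns, no], w)
        assert est.wm_ == pytest.approx(0.11, rel=1e-6)
        assert est.beta_ == pytest.approx(0.13, rel=1e-6)
        assert est.alpha_ == pytest.approx(5.6, rel=1e-6)

    def test_all_zero_other_density_is_degenerate(self):
        ns = np.repeat([2.0, 4.0, 8.0], 4)
        with pytest.raises(FitError, match="not identifiable"):
            BicultureCompetition(b=1.0).fit(
                np.c_[ns, np.zeros_like(ns)], np.full(ns.size, 0.05)
            )

    def test_wald_columns_consistent(self, rng):
        ns = np.tile(np.repeat([2.0, 4.0, 8.0], 3), 3)
        no = np.repeat([2.0, 4.0, 8.0], 9)
        w = predict_biculture(0.11, 0.5, 2.0, 0.97, ns, no)
        w = w * np.exp(rng.normal(0, 0.3, w.size))
        est = BicultureCompetition(b=0.97).fit(np.c_[ns, no], w)
        assert est.t_beta_ == pytest.approx(est.beta_ / est.se_beta_)
        assert est.t_alpha_ == pytest.approx(est.alpha_ / est.se_alpha_)
        assert 0 <= est.p_beta_ <= 1 and 0 <= est.p_alpha_ <= 1
        assert est.df_resid_ == est.n_ - 3


class TestPseudoR2:
    def test_perfect_fit_is_one(self):
        y = np.array([0.1, 0.4, -1.0, 2.0])
        assert pseudo_r2(y, y) == 1.0

    def test_mean_prediction_is_zero(self):
        y = np.array([0.1, 0.4, -1.0, 2.0])
        assert pseudo_r2(y, np.full_like(y, y.mean())) == pytest.approx(0.0)

    def test_constant_observations_undefined(self):
        assert np.isnan(pseudo_r2([1.0, 1.0, 1.0], [1.0, 0.9, 1.1]))


class TestCoefficientTable:
    def test_one_fit_two_rows_with_recomputable_t(self, noise_free_table):
        from addseries.data import split_monoculture_biculture
        from addseries.preprocess import prepare_log_response

        mono, bi = split_monoculture_biculture(noise_free_table)
        mf = fit_monoculture(prepare_log_response(mono), species="VEDU")
        bf = fit_biculture(prepare_log_response(bi), mf.b, species="VEDU")
        table = coefficient_table([bf])
        assert len(table) == 2
        assert table["parameter"].tolist() == ["beta_VEDU", "alpha_VEDU"]
        assert table.loc[0, "t_value"] == pytest.approx(
            round(bf.beta / bf.se_beta, 4), abs=1e-4
        )
        # report precision is 4 decimal places
        assert (table["estimate"] == table["estimate"].round(4)).all()
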
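"""Ordinal CFA: DWLS estimation, corrected statistic, fit indices,
modification indices, and categorical omega."""

import numpy as np
import pytest
from scipy import optimize

from isqkit.cfa import (OrdinalFactorModel, model_df, omega_categorical,
                        omega_from_params, smooth_correlation)
from isqkit.polychoric import PolychoricMatrix, polychoric_matrix
from isqkit.simulate import (SimConfig, simulate_responses, slope_to_loading)


def _corr_matrix(rho, ids=None):
    p = rho.shape[0]
    ids = ids or [f"i{j}" for j in range(p)]
    return PolychoricMatrix(rho, ids, {i: np.zeros(1) for i in ids},
                            np.full((p, p), 0.02), np.full((p, p), 500.0))


@pytest.fixture(scope="module")
def cfa8_doublet(items8):
    cfg = SimConfig(items=items8, n_per_group={"g": 2000}, seed=4,
                    doublets=[(("item2", "item6"), 0.6)])
    X, _ = simulate_responses(cfg)
    return OrdinalFactorModel.from_data(X, n_boot=80, seed=5).fit()


class TestModelDf:
    @pytest.mark.parametrize("p,df", [(20, 170), (8, 20), (3, 0)])
    def test_values(self, p, df):
        assert model_df(p) == df

    def test_too_few_items(self):
        with pytest.raises(ValueError):
            model_df(2)


class TestDwlsFit:
    def test_exact_rank_one_fit(self):
        lam = np.full(6, 0.8)
        R = np.outer(lam, lam)
        np.fill_diagonal(R, 1.0)
        m = len(lam) * (len(lam) - 1) // 2
        model = OrdinalFactorModel(_corr_matrix(R), nobs=500,
                                   gamma=np.eye(m))
        res = model.fit()
        assert res.discrepancy < 1e-12
        assert res.statistic < 1e-6
        assert np.allclose(np.abs(res.loadings_), 0.8, atol=1e-6)
        fi = res.fit_indices()
        assert fi["CFI"] == pytest.approx(1.0)
        assert fi["RMSEA"] == pytest.approx(0.0, abs=1e-6)
        assert fi["SRMR"] < 1e-7

    def test_identity_weight_equals_brute_force(self):
        """DWLS with unit weights is unweighted least squares; compare to an
        independent derivative-free minimizer on a p=4 instance."""
        rng = np.random.default_rng(7)
        lam0 = np.array([0.7, 0.5, 0.8, 0.6])
        R = np.outer(lam0, lam0) + rng.normal(0, 0.02, (4, 4))
        R = (R + R.T) / 2
        np.fill_diagonal(R, 1.0)
        Rm = _corr_matrix(R)
        res = OrdinalFactorModel(Rm, nobs=500,
                                 weights=np.ones(6)).fit()
        pairs = Rm.pair_index()
        r = Rm.offdiag_vector()

        def uls(lam):
            return sum((r[k] - lam[i] * lam[j]) ** 2
                       for k, (i, j) in enumerate(pairs))

        best = None
        for s in ([0.5] * 4, [0.9, 0.4, 0.9, 0.4], lam0):
            out = optimize.minimize(uls, s, method="Nelder-Mead",
                                    options={"xatol": 1e-10, "fatol": 1e-14,
                                             "maxiter": 5000})
            if best is None or out.fun < best.fun:
                best = out
        assert res.discrepancy == pytest.approx(best.fun, abs=1e-8)
        assert np.allclose(np.abs(res.loadings_), np.abs(best.x), atol=1e-4)

    def test_loading_recovery_within_tolerance(self, cfa8_results, items8):
        lam_true = np.array([slope_to_loading(it.slope) for it in items8])
        assert np.max(np.abs(cfa8_results.loadings_ - lam_true)) < 0.05

    def test_communality_is_squared_loading(self, cfa8_results):
        tab = cfa8_results.loading_table()
        assert np.allclose(tab.communality, tab.loading**2, atol=0)
        assert np.allclose(tab.residual_variance, 1 - tab.loading**2)

    def test_corrected_statistic_calibrated(self, cfa8_results):
        # clean one-factor data: corrected T should look like chi2(df)
        assert cfa8_results.df == 20
        assert cfa8_results.pvalue > 0.01
        assert 0.3 < cfa8_results.statistic / cfa8_results.df < 2.5

    def test_heywood_clamped_with_warning(self):
        R = np.full((4, 4), 0.998)
        np.fill_diagonal(R, 1.0)
        with pytest.warns(UserWarning):
            res = OrdinalFactorModel(_corr_matrix(R), nobs=200,
                                     weights=np.ones(6)).fit()
        assert np.all(np.abs(res.loadings_) <= 0.999)

    def test_nan_entries_rejected(self):
        R = np.eye(4)
        R[0, 1] = R[1, 0] = np.nan
        with pytest.raises(ValueError):
            OrdinalFactorModel(_corr_matrix(R), nobs=100)

    def test_smoothing_repairs_indefinite_matrix(self):
        R = np.array([[1.0, 0.95, -0.9], [0.95, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        with pytest.warns(UserWarning):
            S = smooth_correlation(R)
        assert np.linalg.eigvalsh(S).min() > 0
        assert np.allclose(np.diag(S), 1.0)


class TestFitIndices:
    def test_clean_simulation_passes_cutoffs(self, cfa8_results):
        fi = cfa8_results.fit_indices()
        assert fi["CFI"] > 0.95 and fi["TLI"] > 0.95
        assert fi["RMSEA"] < 0.06
        assert fi["SRMR"] < 0.08 and fi["CRMR"] < 0.08
        assert fi["WRMR"] < 1.0
        assert fi["RMSEA_lo"] <= fi["RMSEA"] <= fi["RMSEA_hi"]

    def test_doublet_breaks_rmsea_cutoff(self, cfa8_doublet):
        assert cfa8_doublet.fit_indices()["RMSEA"] > 0.06


class TestModificationIndices:
    def test_null_data_no_epc_flags(self, cfa8_results):
        mi = cfa8_results.modification_indices()
        assert len(mi) == 28
        assert mi.flag.sum() == 0
        assert np.all(mi.mi >= 0)

    def test_doublet_pair_is_top_mi_and_flagged(self, cfa8_doublet):
        mi = cfa8_doublet.modification_indices()
        top = mi.iloc[0]
        assert {top.item_a, top.item_b} == {"item2", "item6"}
        assert top.flag and top.epc > 0.1

    def test_saturated_model_all_zero(self):
        lam = np.array([0.6, 0.7, 0.8])
        R = np.outer(lam, lam)
        np.fill_diagonal(R, 1.0)
        res = OrdinalFactorModel(_corr_matrix(R), nobs=300,
                                 gamma=np.eye(3)).fit()
        mi = res.modification_indices()
        assert np.allclose(mi.mi, 0.0, atol=1e-6)

    def test_flag_set_invariant_to_item_order(self, items8):
        cfg = SimConfig(items=items8, n_per_group={"g": 1200}, seed=14,
                        doublets=[(("item2", "item6"), 0.6)])
        X, _ = simulate_responses(cfg)
        perm = ["item6", "item3", "item8", "item1", "item5", "item2",
                "item7", "item4"]
        flags = []
        for order in (X.item_ids, perm):
            res = OrdinalFactorModel.from_data(X.select_items(order),
                                               n_boot=60, seed=15).fit()
            mi = res.modification_indices()
            flags.append({frozenset((a, b))
                          for a, b in zip(mi[mi.flag].item_a,
                                          mi[mi.flag].item_b)})
        assert flags[0] == flags[1]


class TestOmega:
    def test_vanishing_loadings_give_zero_omega(self):
        taus = [np.array([-1.0, 0.0, 1.0])] * 5
        w = omega_from_params(np.full(5, 1e-4), taus)
        assert w == pytest.approx(0.0, abs=1e-4)

    def test_item_order_permutation_invariant(self):
        rng = np.random.default_rng(11)
        lam = rng.uniform(0.4, 0.9, 6)
        taus = [np.sort(rng.normal(0, 1, 4)) for _ in range(6)]
        w1 = omega_from_params(lam, taus)
        order = [3, 1, 5, 0, 2, 4]
        w2 = omega_from_params(lam[order], [taus[i] for i in order])
        assert w1 == pytest.approx(w2, abs=1e-12)

    def test_more_reliable_with_higher_loadings(self):
        taus = [np.array([-1.0, 0.0, 1.0])] * 6
        assert omega_from_params(np.full(6, 0.8), taus) > \
            omega_from_params(np.full(6, 0.4), taus)

    def test_population_value_within_bootstrap_ci(self, cfa8_results,
                                                  grm8_sim, items8):
        """Fitted omega's bootstrap CI covers the population value of the
        estimator, obtained by running the same threshold/polychoric/fit
        chain on an n=200000 sample from the generating model."""
        Xbig, _ = simulate_responses(
            SimConfig(items=items8, n_per_group={"g": 200_000}, seed=77))
        Rbig = polychoric_matrix(Xbig)
        big = OrdinalFactorModel(Rbig, Xbig.n,
                                 weights=np.ones(len(Rbig.pair_index()))).fit()
        pop = omega_from_params(big.loadings_,
                                [Rbig.thresholds[i] for i in Rbig.item_ids])
        X, _ = grm8_sim
        rel = omega_categorical(cfa8_results, X, n_boot=80, seed=21)
        assert 0.7 < rel.omega < 1.0
        assert rel.ci[0] <= pop <= rel.ci[1]
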
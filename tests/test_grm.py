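"""Graded response model: EM estimation, limited-information fit, local
dependence, EAP scoring, reliability, and curves."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from isqkit.data import ResponseMatrix
from isqkit.grm import (ConvergenceError, GradedResponseModel, GRMResults,
                        load_calibration)
from isqkit.simulate import (ItemParams, SimConfig, default_items,
                             grm_category_probs, simulate_responses)


def _calibration(items, n_quad=61, bound=6.0):
    return load_calibration({"items": [it.to_dict() for it in items],
                             "quadrature": {"n_nodes": n_quad,
                                            "bound": bound}})


class TestFit:
    def test_parameter_recovery(self, grm8_fit, items8):
        a_true = np.array([it.slope for it in items8])
        a_est = np.array([it.slope for it in grm8_fit.item_params])
        b_true = np.vstack([it.thresholds for it in items8])
        b_est = np.vstack([it.thresholds for it in grm8_fit.item_params])
        assert np.sqrt(np.mean((a_est - a_true) ** 2)) < 0.15
        assert np.sqrt(np.mean((b_est - b_true) ** 2)) < 0.12

    def test_loglik_nondecreasing(self, grm8_fit):
        incr = np.diff(grm8_fit.ll_trace)
        assert np.all(incr > -1e-6 * np.abs(grm8_fit.ll_trace[0]))

    def test_thresholds_ordered_post_fit(self, grm8_fit):
        for it in grm8_fit.item_params:
            assert np.all(np.diff(it.thresholds) > 0)

    def test_duplicating_persons_leaves_estimates_unchanged(self):
        items = default_items(4, 5, seed=31)
        cfg = SimConfig(items=items, n_per_group={"g": 400}, seed=32)
        X, _ = simulate_responses(cfg)
        X2 = ResponseMatrix(np.vstack([X.values, X.values]), X.item_ids,
                            n_categories=X.n_categories)
        r1 = GradedResponseModel(X).fit()
        r2 = GradedResponseModel(X2).fit()
        for a, b in zip(r1.item_params, r2.item_params):
            assert a.slope == pytest.approx(b.slope, abs=1e-8)
            assert np.allclose(a.thresholds, b.thresholds, atol=1e-8)

    def test_single_binary_item_matches_grid_search_oracle(self):
        """One 2-category item: EM estimate vs brute-force maximization of
        the marginal likelihood on a parameter grid."""
        item = ItemParams("x", 1.4, np.array([0.45]))
        cfg = SimConfig(items=[item], n_per_group={"g": 1500}, seed=33)
        X, _ = simulate_responses(cfg)
        res = GradedResponseModel(X).fit()
        grid = np.linspace(-6, 6, 61)
        w = np.exp(-0.5 * grid**2)
        w /= w.sum()
        n1 = int(np.sum(X.values == 2))
        n0 = X.n - n1

        def marg_ll(a, b):
            p = 1.0 / (1.0 + np.exp(-a * (grid - b)))
            p2 = np.sum(w * p)
            return n1 * np.log(p2) + n0 * np.log1p(-p2)

        avals = np.arange(0.2, 4.0, 0.02)
        bvals = np.arange(-2.0, 2.0, 0.02)
        lls = np.array([[marg_ll(a, b) for b in bvals] for a in avals])
        est = res.item_params[0]
        # a single binary item identifies only P(X=2): the likelihood is a
        # ridge in (a, b); the EM solution must attain the grid maximum and
        # imply the observed response rate
        assert marg_ll(est.slope, est.thresholds[0]) >= lls.max() - 1e-4
        p = 1.0 / (1.0 + np.exp(-est.slope * (grid - est.thresholds[0])))
        assert np.sum(w * p) == pytest.approx(n1 / X.n, abs=1e-3)

    def test_sparse_category_rejected(self):
        vals = np.full((200, 2), 3.0)
        X = ResponseMatrix(vals, ["a", "b"], n_categories=3)
        with pytest.raises(ValueError):
            GradedResponseModel(X)

    def test_nonconvergence_raises_with_trace(self, grm8_sim):
        X, _ = grm8_sim
        with pytest.raises(ConvergenceError) as exc:
            GradedResponseModel(X).fit(maxiter=2)
        assert exc.value.trace is not None

    def test_standard_errors_reasonable(self, grm8_fit):
        se = grm8_fit.standard_errors()
        vals = np.array(list(se.values()))
        assert np.all((vals > 0.005) & (vals < 0.5))


class TestEapScoring:
    def test_all_missing_returns_prior(self, grm8_fit):
        out = grm8_fit.eap_score(np.full(8, np.nan))
        assert out["theta"] == pytest.approx(0.0, abs=1e-10)
        assert out["psd"] == pytest.approx(1.0, abs=1e-3)
        assert out["reliability"] == pytest.approx(0.0, abs=2e-3)
        assert out["no_information"]

    def test_extreme_patterns_symmetric_for_symmetric_items(self):
        items = [ItemParams(f"i{j}", 1.5, np.array([-1.0, 0.0, 1.0]))
                 for j in range(5)]
        res = _calibration(items)
        lo = res.eap_score(np.ones(5))
        hi = res.eap_score(np.full(5, 4.0))
        assert lo["theta"] < 0 < hi["theta"]
        assert lo["theta"] == pytest.approx(-hi["theta"], abs=1e-10)

    def test_matches_dense_grid_oracle(self, grm8_fit, grm8_sim):
        X, _ = grm8_sim
        grid = np.linspace(-6, 6, 2001)
        w = np.exp(-0.5 * grid**2)
        rng = np.random.default_rng(5)
        for i in rng.integers(0, X.n, 20):
            pat = X.values[i]
            out = grm8_fit.eap_score(pat)
            logp = np.log(w).copy()
            for j, it in enumerate(grm8_fit.item_params):
                P = grm_category_probs(grid, it)
                logp += np.log(P[:, int(pat[j]) - 1])
            post = np.exp(logp - logp.max())
            post /= post.sum()
            th = float(post @ grid)
            psd = float(np.sqrt(post @ grid**2 - th**2))
            assert out["theta"] == pytest.approx(th, abs=1e-4)
            assert out["psd"] == pytest.approx(psd, abs=1e-4)

    def test_t_score_affine(self, grm8_fit, grm8_sim):
        X, _ = grm8_sim
        sc = grm8_fit.eap_scores(X)
        assert np.allclose(sc.t_score, 50 + 10 * sc.theta)
        assert np.all(sc.psd > 0)
        assert np.all(sc.reliability < 1)

    def test_out_of_range_response_rejected(self, grm8_fit):
        with pytest.raises(ValueError):
            grm8_fit.eap_score(np.full(8, 9.0))

    def test_spearman_with_sum_score(self, grm8_fit, grm8_sim):
        X, _ = grm8_sim
        sc = grm8_fit.eap_scores(X)
        rho = spearmanr(sc.theta, X.values.sum(axis=1)).statistic
        assert rho > 0.98


class TestC2:
    def test_df_is_pair_count_minus_items(self, grm8_fit):
        st = grm8_fit.c2()
        assert st.df == 8 * 7 // 2 - 8 == 20
        assert st.statistic >= 0
        assert 0 <= st.pvalue <= 1

    def test_clean_data_fits_well(self, grm8_fit):
        st = grm8_fit.c2()
        assert st.rmsea < 0.06
        assert st.cfi > 0.95
        assert st.srmr < 0.08

    def test_pvalues_calibrated_under_the_model(self):
        """Parametric-bootstrap calibration: rejection rate at alpha=0.05
        within 2 Monte-Carlo SEs over 100 replicates."""
        items = default_items(6, 5, seed=41)
        rej = 0
        nrep = 100
        for rep in range(nrep):
            cfg = SimConfig(items=items, n_per_group={"g": 1000},
                            seed=9000 + rep)
            X, _ = simulate_responses(cfg)
            res = GradedResponseModel(X, n_quad=31).fit()
            rej += res.c2(X).pvalue < 0.05
        mc_se = np.sqrt(0.05 * 0.95 / nrep)
        assert rej / nrep <= 0.05 + 2 * mc_se + 1e-9

    def test_doublet_inflates_rmsea(self, grm8_fit, items8):
        cfg = SimConfig(items=items8, n_per_group={"g": 2000}, seed=4,
                        doublets=[(("item2", "item6"), 0.6)])
        Xd, _ = simulate_responses(cfg)
        resd = GradedResponseModel(Xd).fit()
        assert resd.c2(Xd).rmsea > grm8_fit.c2().rmsea


class TestLocalDependence:
    def test_clean_data_below_threshold(self, grm8_fit):
        ld = grm8_fit.ld_chi2()
        off = ld.values[~np.isnan(ld.values)]
        assert np.all(off < 10.0)
        assert ld.flagged_pairs() == []

    def test_doublet_pair_is_maximum_and_flagged(self, items8):
        cfg = SimConfig(items=items8, n_per_group={"g": 2000}, seed=44,
                        doublets=[(("item3", "item7"), 0.6)])
        X, _ = simulate_responses(cfg)
        res = GradedResponseModel(X).fit()
        ld = res.ld_chi2(X)
        a, b, v = ld.max_pair()
        assert {a, b} == {"item3", "item7"}
        assert v > 10.0

    def test_two_items_symmetric_storage(self):
        items = default_items(2, 5, seed=45)
        cfg = SimConfig(items=items, n_per_group={"g": 800}, seed=46)
        X, _ = simulate_responses(cfg)
        # a 2-item GRM is on the edge of identification; a loose tolerance
        # suffices for checking the LD bookkeeping
        res = GradedResponseModel(X).fit(tol=2e-3)
        ld = res.ld_chi2(X)
        assert ld.values[0, 1] == ld.values[1, 0]
        assert np.isnan(ld.values[0, 0])


class TestMarginalReliability:
    def test_weak_items_give_low_reliability(self):
        weak = [ItemParams(f"i{j}", 0.3, np.array([-1.0, 0.0, 1.0]))
                for j in range(5)]
        strong = [ItemParams(f"i{j}", 2.5, np.array([-1.0, 0.0, 1.0]))
                  for j in range(5)]
        cfg = SimConfig(items=strong, n_per_group={"g": 1000}, seed=47)
        X, _ = simulate_responses(cfg)
        r_strong = _calibration(strong).marginal_reliability(X, n_boot=50)
        cfgw = SimConfig(items=weak, n_per_group={"g": 1000}, seed=47)
        Xw, _ = simulate_responses(cfgw)
        r_weak = _calibration(weak).marginal_reliability(Xw, n_boot=50)
        assert r_weak.rho < 0.45 < r_strong.rho
        assert r_weak.ci[0] <= r_weak.rho <= r_weak.ci[1]

    def test_additional_informative_item_increases_reliability(self):
        items9 = default_items(9, 5, seed=48)
        cfg = SimConfig(items=items9, n_per_group={"g": 1500}, seed=49)
        X9, _ = simulate_responses(cfg)
        X8 = X9.select_items([f"item{j}" for j in range(1, 9)])
        rho9 = _calibration(items9).marginal_reliability(X9, n_boot=30).rho
        rho8 = _calibration(items9[:8]).marginal_reliability(X8, n_boot=30).rho
        assert rho9 > rho8

    def test_population_oracle_agreement(self, grm8_fit, grm8_sim, items8):
        """Sample reliability matches the same statistic computed on an
        n=100000 draw from the generating model (population oracle)."""
        X, _ = grm8_sim
        rel = grm8_fit.marginal_reliability(X, n_boot=200, seed=50)
        Xbig, _ = simulate_responses(
            SimConfig(items=items8, n_per_group={"g": 100_000}, seed=51))
        sc = _calibration(items8).eap_scores(Xbig)
        v = np.var(sc.theta)
        pop = v / (v + np.mean(sc.psd**2))
        assert rel.ci[0] - 0.01 <= pop <= rel.ci[1] + 0.01


class TestCurves:
    def test_category_curves_sum_to_one(self, grm8_fit):
        curves = grm8_fit.item_curves()
        pcols = [c for c in curves.columns if c.startswith("P")]
        assert np.allclose(curves[pcols].sum(axis=1), 1.0, atol=1e-10)

    def test_binary_item_information_peaks_at_threshold(self):
        it = ItemParams("x", 1.8, np.array([0.7]))
        res = _calibration([it])
        grid = np.linspace(-4, 4, 1601)
        curves = res.item_curves(grid)
        peak = grid[curves["information"].to_numpy().argmax()]
        assert abs(peak - 0.7) < 0.01

    def test_doubling_slope_raises_peak_information(self):
        lo = ItemParams("x", 1.0, np.array([-0.5, 0.5]))
        hi = ItemParams("x", 2.0, np.array([-0.5, 0.5]))
        grid = np.linspace(-4, 4, 161)
        pk = [_calibration([it]).item_curves(grid)["information"].max()
              for it in (lo, hi)]
        assert pk[1] > pk[0]

    def test_total_information_is_item_sum(self, grm8_fit):
        grid = np.linspace(-3, 3, 121)
        total = grm8_fit.total_information(grid)
        curves = grm8_fit.item_curves(grid)
        assert np.allclose(total,
                           curves.groupby("theta")["information"].sum())


class TestCalibrationArtifact:
    def test_roundtrip_scores_identical(self, grm8_fit, grm8_sim, tmp_path):
        X, _ = grm8_sim
        path = tmp_path / "cal.json"
        grm8_fit.save_calibration(path, metadata={"n": X.n})
        reloaded = load_calibration(path)
        s1 = grm8_fit.eap_scores(X)
        s2 = reloaded.eap_scores(X)
        assert np.max(np.abs(s1.theta - s2.theta)) < 1e-12
        assert np.max(np.abs(s1.psd - s2.psd)) < 1e-12
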
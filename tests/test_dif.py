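"""Group construction, multigroup GRM, the iterative Wald DIF procedure,
and the demographic regression."""

import numpy as np
import pandas as pd
import pytest

from isqkit.dif import (MultigroupGRMModel, iterative_wald_dif, make_groups,
                        regress_scores)
from isqkit.simulate import (DifEffect, ItemParams, SimConfig, default_items,
                             simulate_responses)


@pytest.fixture(scope="module")
def items4():
    return default_items(4, 4, seed=22)


@pytest.fixture(scope="module")
def null_groups_sim(items4):
    cfg = SimConfig(items=items4, n_per_group={"ref": 600, "foc": 600},
                    seed=71)
    return simulate_responses(cfg)


class TestMakeGroups:
    def test_age_boundary_in_lower_group(self):
        cov = pd.DataFrame({"age": [39.0, 40.0, 41.0] * 20})
        gs = make_groups(cov, "age", cutpoint=40)
        labels = gs.labels.to_numpy()
        assert labels[0] == labels[1] == "age<=40"
        assert labels[2] == "age>40"

    def test_income_boundary(self):
        cov = pd.DataFrame({"income": [20_000.0, 50_000.0, 80_000.0] * 20})
        gs = make_groups(cov, "income", cutpoint=50_000)
        assert gs.labels.iloc[1] == "income<=50000"

    def test_single_level_covariate_rejected(self):
        cov = pd.DataFrame({"sex": ["M"] * 100})
        with pytest.raises(ValueError):
            make_groups(cov, "sex")

    def test_tiny_group_rejected(self):
        cov = pd.DataFrame({"sex": ["M"] * 95 + ["F"] * 5})
        with pytest.raises(ValueError):
            make_groups(cov, "sex")

    def test_multilevel_needs_mapping(self):
        cov = pd.DataFrame({"gender": (["cis_male", "cis_female",
                                        "nonbinary"] * 40)})
        with pytest.raises(ValueError):
            make_groups(cov, "gender")
        gs = make_groups(cov, "gender",
                         mapping={"cis_male": "male", "cis_female": "female",
                                  "nonbinary": None})
        assert gs.labels.isna().sum() == 40
        assert set(gs.group_names) == {"male", "female"}

    def test_missingness_over_ten_percent_rejected(self):
        cov = pd.DataFrame({"age": [30.0] * 80 + [np.nan] * 20})
        with pytest.raises(ValueError):
            make_groups(cov, "age", cutpoint=40)


class TestMultigroupModel:
    def test_focal_mean_recovery(self, items4):
        cfg = SimConfig(items=items4, n_per_group={"r": 1000, "f": 1000},
                        group_theta_means={"r": 0.0, "f": 0.5}, seed=72)
        X, truth = simulate_responses(cfg)
        fit = MultigroupGRMModel(X, truth["group"], reference="r",
                                 n_quad=41).fit()
        assert abs(fit.focal_mean - 0.5) < 0.1
        assert abs(fit.focal_sd - 1.0) < 0.12

    def test_released_item_estimates_close_under_null(self, null_groups_sim):
        X, truth = null_groups_sim
        fit = MultigroupGRMModel(X, truth["group"], reference="ref",
                                 n_quad=31).fit(free_items={"item2"})
        a_r = fit.params["item2"]["ref"].slope
        a_f = fit.params["item2"]["foc"].slope
        assert abs(a_r - a_f) < 0.4
        stat, df, p, _ = fit.wald_test("item2")
        assert df == 1 + 3
        assert p > 0.001

    def test_identical_groups_give_null_wald(self, items4):
        cfg = SimConfig(items=items4, n_per_group={"g": 700}, seed=73)
        X, _ = simulate_responses(cfg)
        import numpy as np
        from isqkit.data import ResponseMatrix
        X2 = ResponseMatrix(np.vstack([X.values, X.values]), X.item_ids,
                            n_categories=X.n_categories)
        labels = np.array(["a"] * X.n + ["b"] * X.n)
        fit = MultigroupGRMModel(X2, labels, reference="a",
                                 n_quad=31).fit(free_items={"item3"})
        stat, _, p, _ = fit.wald_test("item3")
        assert stat < 0.1
        assert abs(fit.focal_mean) < 0.02

    def test_group_relabeling_flips_mean_keeps_wald(self, items4):
        cfg = SimConfig(items=items4, n_per_group={"a": 600, "b": 600},
                        group_theta_means={"a": 0.0, "b": 0.3}, seed=74)
        X, truth = simulate_responses(cfg)
        f1 = MultigroupGRMModel(X, truth["group"], reference="a",
                                n_quad=31).fit(free_items={"item1"})
        f2 = MultigroupGRMModel(X, truth["group"], reference="b",
                                n_quad=31).fit(free_items={"item1"})
        s1, _, _, _ = f1.wald_test("item1")
        s2, _, _, _ = f2.wald_test("item1")
        # latent means on a common scale: mu_b|a ~= -mu_a|b / sd
        assert np.sign(f1.focal_mean) == -np.sign(f2.focal_mean)
        assert abs(f1.focal_mean + f2.focal_mean * f1.focal_sd) < 0.05
        assert s1 == pytest.approx(s2, rel=0.25, abs=0.5)

    def test_three_groups_rejected(self, items4):
        cfg = SimConfig(items=items4, n_per_group={"a": 100, "b": 100,
                                                   "c": 100}, seed=75)
        X, truth = simulate_responses(cfg)
        with pytest.raises(ValueError):
            MultigroupGRMModel(X, truth["group"])


class TestIterativeWald:
    def test_no_flags_without_dif(self, null_groups_sim):
        X, truth = null_groups_sim
        res = iterative_wald_dif(X, truth["group"], reference="ref",
                                 n_quad=21, em_tol=5e-4)
        assert res.flagged == []
        assert res.anchors == X.item_ids
        assert len(res.table) == 4

    def test_slope_dif_detected_and_followed_up(self, items4):
        items = [ItemParams(it.item_id, 1.0 if it.item_id == "item2"
                            else it.slope, it.thresholds) for it in items4]
        cfg = SimConfig(items=items, n_per_group={"r": 500, "f": 500},
                        seed=76, dif_spec=[DifEffect("item2", "slope",
                                                     0.8, "f")])
        X, truth = simulate_responses(cfg)
        res = iterative_wald_dif(X, truth["group"], reference="r",
                                 n_quad=21, em_tol=5e-4)
        assert res.flagged == ["item2"]
        assert "item2" not in res.anchors
        fu = res.followups["item2"]
        assert fu.loc[fu.parameter == "slope", "p"].iloc[0] < 0.05

    def test_fdr_adjustment_monotone(self, null_groups_sim):
        X, truth = null_groups_sim
        res = iterative_wald_dif(X, truth["group"], reference="ref",
                                 n_quad=21, em_tol=5e-4)
        t = res.table.sort_values("p")
        assert np.all(np.diff(t.p_fdr) >= -1e-12)
        assert np.all(t.p_fdr >= t.p - 1e-12)

    def test_too_few_items_rejected(self, items4, null_groups_sim):
        X, truth = null_groups_sim
        with pytest.raises(ValueError):
            iterative_wald_dif(X.select_items(X.item_ids[:3]), truth["group"])


class TestRegression:
    def test_independent_scores_yield_null_r2(self):
        rng = np.random.default_rng(80)
        n = 2000
        scores = pd.DataFrame({"theta": rng.normal(0, 1, n)})
        cov = pd.DataFrame({"age": rng.uniform(18, 70, n),
                            "sex": rng.choice(["M", "F"], n)})
        reg = regress_scores(scores, cov)
        assert reg.rsquared < 0.01
        assert reg.n_used == n

    def test_injected_sex_shift_recovered(self):
        rng = np.random.default_rng(81)
        n = 2000
        sex = rng.choice(["M", "F"], n)
        theta = rng.normal(0, 1, n) + 0.6 * (sex == "F")
        cov = pd.DataFrame({"age": rng.uniform(18, 70, n), "sex": sex})
        reg = regress_scores(pd.DataFrame({"theta": theta}), cov)
        assert abs(reg.beta_f_minus_m - 0.6) < 0.1
        assert reg.pvalues["sex_F"] < 0.001

    def test_nonbinary_entries_excluded_and_counted(self):
        rng = np.random.default_rng(82)
        n = 300
        sex = np.array(["M"] * 140 + ["F"] * 140 + ["X"] * 20)
        cov = pd.DataFrame({"age": rng.uniform(18, 70, n), "sex": sex})
        reg = regress_scores(pd.DataFrame({"theta": rng.normal(0, 1, n)}), cov)
        assert reg.n_excluded == 20

    def test_constant_scores_rejected(self):
        cov = pd.DataFrame({"age": np.linspace(20, 60, 100),
                            "sex": ["M", "F"] * 50})
        with pytest.raises(ValueError):
            regress_scores(pd.DataFrame({"theta": np.zeros(100)}), cov)
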
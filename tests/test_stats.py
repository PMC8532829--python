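"""Regression, ANOVA/Tukey and stepwise selection against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fatgrade import stats


def _df(**cols):
    return pd.DataFrame(cols)


class TestOlsFit:
    def test_exact_line(self):
        x = np.arange(1.0, 6.0)
        fit = stats.ols_fit(2 * x, _df(x=x))
        assert fit.coef[1] == pytest.approx(2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0) and fit.rmse == pytest.approx(0.0, abs=1e-10)

    def test_hand_worked_example(self):
        # points (1,1),(2,3),(3,2),(4,5): slope 1.1, intercept 0, R^2 = 6.05/8.75
        fit = stats.ols_fit([1, 3, 2, 5], _df(x=[1.0, 2.0, 3.0, 4.0]))
        assert fit.coef[1] == pytest.approx(1.1)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r2 == pytest.approx(6.05 / 8.75)

    def test_constant_predictor_errors(self):
        with pytest.raises(ValueError, match="collinear"):
            stats.ols_fit([1, 2, 3, 4, 5], _df(x=np.ones(5)))

    def test_too_few_observations(self):
        with pytest.raises(ValueError, match="too few"):
            stats.ols_fit([1, 2, 3], _df(a=[1, 2, 3], b=[2, 1, 4]))

    def test_matches_normal_equations_oracle(self):
        """100 random small problems: coefficients, R^2 and RMSE agree with
        the closed-form normal-equations solution to 1e-8."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(8, 21))
            k = int(rng.integers(1, 4))
            X = rng.normal(size=(n, k))
            y = rng.normal(size=n) + X @ rng.normal(size=k)
            fit = stats.ols_fit(y, pd.DataFrame(X, columns=[f"x{i}" for i in range(k)]))
            M = np.column_stack([np.ones(n), X])
            beta = np.linalg.solve(M.T @ M, M.T @ y)
            np.testing.assert_allclose(fit.coef, beta, atol=1e-8)
            resid = y - M @ beta
            sse = resid @ resid
            sst = ((y - y.mean()) ** 2).sum()
            assert fit.r2 == pytest.approx(1 - sse / sst, abs=1e-8)
            assert fit.rmse == pytest.approx(np.sqrt(sse / (n - k - 1)), abs=1e-8)

    def test_r2_is_squared_correlation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        y = 1.5 * x + rng.normal(size=30)
        fit = stats.ols_fit(y, _df(x=x))
        assert fit.r2 == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2, abs=1e-10)

    def test_adding_term_never_decreases_r2(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        y = X["a"] + rng.normal(size=40)
        r2 = [stats.ols_fit(y, X[list("abc")[: k + 1]]).r2 for k in range(3)]
        assert r2[0] <= r2[1] + 1e-12 and r2[1] <= r2[2] + 1e-12


class TestAnova:
    def test_hand_decomposition(self):
        res = stats.one_way_anova([1, 2, 3, 2, 3, 4], ["g1"] * 3 + ["g2"] * 3)
        assert res.f_stat == pytest.approx(1.5)
        assert res.p_value == pytest.approx(float(sps.f.sf(1.5, 1, 4)))

    def test_identical_groups_f_zero(self):
        res = stats.one_way_anova([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert res.f_stat == pytest.approx(0.0, abs=1e-12)

    def test_single_group_errors(self):
        with pytest.raises(ValueError, match="2 groups"):
            stats.one_way_anova([1, 2, 3], ["a", "a", "a"])

    def test_tiny_group_errors(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            stats.one_way_anova([1, 2, 3], ["a", "a", "b"])


class TestTukey:
    def test_separated_groups_get_distinct_letters(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([rng.normal(0, 1, 10), rng.normal(100, 1, 10)])
        res = stats.tukey_hsd(vals, ["lo"] * 10 + ["hi"] * 10)
        assert set(res.letters.values()) == {"a", "b"}
        assert res.letters["lo"] != res.letters["hi"]

    def test_identical_groups_share_letter(self):
        res = stats.tukey_hsd([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert res.letters["a"] == res.letters["b"]

    def test_degenerate_mse_errors(self):
        with pytest.raises(ValueError, match="degenerate MSE"):
            stats.tukey_hsd([5, 5, 5, 7, 7, 7], ["a"] * 3 + ["b"] * 3)

    def test_pairwise_matches_studentized_range_oracle(self):
        """Four unequal groups: every pairwise p recomputed directly from the
        studentized-range distribution (Tukey-Kramer), and cross-checked
        against scipy's independent Tukey HSD implementation."""
        rng = np.random.default_rng(3)
        groups = {
            "a": rng.normal(0.0, 1.0, 5),
            "b": rng.normal(0.8, 1.0, 7),
            "c": rng.normal(2.5, 1.0, 4),
            "d": rng.normal(2.6, 1.0, 6),
        }
        vals = np.concatenate(list(groups.values()))
        labs = sum([[k] * len(v) for k, v in groups.items()], [])
        res = stats.tukey_hsd(vals, labs)

        k = len(groups)
        dfw = sum(len(v) - 1 for v in groups.values())
        mse = sum(((v - v.mean()) ** 2).sum() for v in groups.values()) / dfw
        for a, b in itertools.combinations(groups, 2):
            va, vb = groups[a], groups[b]
            q = abs(va.mean() - vb.mean()) / np.sqrt(mse / 2 * (1 / len(va) + 1 / len(vb)))
            p_oracle = float(sps.studentized_range.sf(q, k, dfw))
            assert res.pairwise_p[frozenset((a, b))] == pytest.approx(p_oracle, abs=1e-12)

        scipy_res = sps.tukey_hsd(*groups.values())
        names = list(groups)
        for i, j in itertools.combinations(range(k), 2):
            mine = res.pairwise_p[frozenset((names[i], names[j]))]
            assert mine == pytest.approx(scipy_res.pvalue[i, j], abs=1e-8)

    def test_letters_encode_pairwise_decisions(self):
        rng = np.random.default_rng(8)
        vals = np.concatenate(
            [rng.normal(0, 1, 8), rng.normal(1.2, 1, 8), rng.normal(6, 1, 8)]
        )
        labs = ["a"] * 8 + ["b"] * 8 + ["c"] * 8
        res = stats.tukey_hsd(vals, labs)
        for g1, g2 in itertools.combinations("abc", 2):
            share = bool(set(res.letters[g1]) & set(res.letters[g2]))
            differs = res.pairwise_p[frozenset((g1, g2))] < res.alpha
            assert share != differs


class TestFeatureSet:
    def test_identity_counts(self):
        t = _df(a=[1.0, 2, 3], b=[2.0, 1, 5], c=[0.5, 4, 2])
        spec = stats.FeatureSpec(base=("a", "b", "c"))
        _, names = stats.build_feature_set(t, spec)
        assert names == ["a", "b", "c"]
        spec3 = stats.FeatureSpec(base=("a", "b", "c"), interaction_order=3)
        design, names = stats.build_feature_set(t, spec3)
        assert len(names) == 7  # 3 singles + 3 pairs + 1 triple
        np.testing.assert_allclose(design["a:b:c"], t["a"] * t["b"] * t["c"])

    def test_log_of_nonpositive_errors(self):
        t = _df(a=[1.0, 0.0, 3.0])
        spec = stats.FeatureSpec(base=("a",), transforms=("log10",))
        with pytest.raises(ValueError, match="'a'"):
            stats.build_feature_set(t, spec)

    def test_transform_names(self):
        t = _df(a=[1.0, 2, 3])
        spec = stats.FeatureSpec(base=("a",), transforms=("identity", "square", "log10", "ln"))
        design, names = stats.build_feature_set(t, spec)
        assert names == ["a", "a^2", "log10(a)", "ln(a)"]
        np.testing.assert_allclose(design["a^2"], t["a"] ** 2)


class TestStepwise:
    def test_exact_single_truth(self):
        rng = np.random.default_rng(5)
        cand = pd.DataFrame(rng.normal(size=(40, 3)), columns=["x1", "x2", "x3"])
        fit = stats.stepwise_select(3.0 * cand["x1"], cand)
        assert fit.terms == ("x1",)
        assert fit.coef[1] == pytest.approx(3.0, abs=1e-10)

    def test_retention_rule_holds(self):
        rng = np.random.default_rng(6)
        for seed in range(5):
            r = np.random.default_rng(seed)
            cand = pd.DataFrame(r.normal(size=(50, 4)), columns=list("wxyz"))
            y = 0.8 * cand["w"] - 0.5 * cand["y"] + r.normal(size=50)
            fit = stats.stepwise_select(y, cand)
            assert all(p < 0.05 for p in fit.pvalues[1:])

    def test_pure_noise_contract(self):
        rng = np.random.default_rng(0)
        cand = pd.DataFrame(rng.normal(size=(50, 3)), columns=["a", "b", "c"])
        fit = stats.stepwise_select(rng.normal(size=50), cand)
        assert fit.terms == () or all(p < 0.05 for p in fit.pvalues[1:])

    def test_matches_all_subsets_oracle(self):
        """n=30, 3 candidates, known 2-term truth: the stepwise answer equals
        the best exhaustive subset whose every term passes the retention rule."""
        for seed in range(8):
            rng = np.random.default_rng(100 + seed)
            cand = pd.DataFrame(rng.normal(size=(30, 3)), columns=["x1", "x2", "x3"])
            y = 2.0 * cand["x1"] - 1.5 * cand["x2"] + rng.normal(size=30)
            fit = stats.stepwise_select(y, cand)

            best, best_r2 = (), -1.0
            for k in range(4):
                for combo in itertools.combinations(cand.columns, k):
                    sub = stats.ols_fit(y, cand[list(combo)])
                    if all(p < 0.05 for p in sub.pvalues[1:]) and sub.r2 > best_r2:
                        best, best_r2 = combo, sub.r2
            assert set(fit.terms) == set(best)

    def test_collinear_candidates_skipped(self):
        """log10 and ln of the same variable are exactly collinear; stepwise
        must pick one and never crash on the other."""
        rng = np.random.default_rng(9)
        x = rng.uniform(1, 10, size=40)
        cand = pd.DataFrame({"log10(x)": np.log10(x), "ln(x)": np.log(x)})
        y = 2.0 * np.log(x) + 0.05 * rng.normal(size=40)
        fit = stats.stepwise_select(y, cand)
        assert len(fit.terms) == 1


class TestPredict:
    def test_intercept_only_constant(self):
        fit = stats.ols_fit([4.0, 5.0, 6.0], pd.DataFrame(index=range(3)))
        pred = stats.predict_cutting_fat(fit, pd.DataFrame(index=range(4)))
        np.testing.assert_allclose(pred, 5.0)

    def test_training_residuals_center_on_zero(self):
        rng = np.random.default_rng(4)
        t = _df(x=rng.uniform(1, 5, 30), z=rng.uniform(1, 5, 30))
        y = 1 + 2 * t["x"] - t["z"] + rng.normal(size=30)
        fit = stats.ols_fit(y, t)
        resid = y - stats.predict_cutting_fat(fit, t)
        assert abs(resid.mean()) < 1e-10

    def test_hand_evaluation_with_transforms(self):
        rng = np.random.default_rng(7)
        t = _df(u=rng.uniform(1, 4, 20), v=rng.uniform(1, 4, 20))
        spec = stats.FeatureSpec(base=("u", "v"), transforms=("identity", "log10"), interaction_order=2)
        design, _ = stats.build_feature_set(t, spec)
        y = design @ rng.normal(size=design.shape[1]) + rng.normal(size=20)
        fit = stats.ols_fit(y, design[["u", "log10(v)", "u:log10(v)"]])
        new = t.head(3)
        byhand = (
            fit.intercept
            + fit.coef[1] * new["u"]
            + fit.coef[2] * np.log10(new["v"])
            + fit.coef[3] * new["u"] * np.log10(new["v"])
        )
        np.testing.assert_allclose(stats.predict_cutting_fat(fit, new), byhand, atol=1e-12)

    def test_missing_column_errors(self):
        fit = stats.ols_fit([1.0, 2, 3, 5, 4], _df(x=[1.0, 2, 3, 4, 5]))
        with pytest.raises(KeyError, match="'x'"):
            stats.predict_cutting_fat(fit, _df(z=[1.0]))
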
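import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from focalenergy.screening import (
    classify_fit,
    collinearity_gate,
    fit_gaussian_glm,
    log1p_transform,
    mann_whitney_z,
    pearson_screen,
    signed_cuberoot,
    student_t,
)


class TestTransforms:
    @pytest.mark.parametrize("x,expected", [
        (0.0, 0.0),
        (math.e - 1.0, 1.0),
        (9.0, math.log(10.0)),
    ])
    def test_log1p(self, x, expected):
        assert log1p_transform(x) == pytest.approx(expected, rel=1e-12)

    def test_log1p_domain(self):
        with pytest.raises(ValueError):
            log1p_transform(-1.5)

    @pytest.mark.parametrize("x,expected", [
        (0.0, 0.0), (-8.0, -2.0), (8.0, 2.0),
        (45.327, 45.327 ** (1.0 / 3.0)),
    ])
    def test_cuberoot(self, x, expected):
        assert signed_cuberoot(x) == pytest.approx(expected, rel=1e-12)

    def test_cuberoot_odd_function(self):
        xs = np.linspace(-20, 20, 41)
        np.testing.assert_allclose(signed_cuberoot(-xs), -signed_cuberoot(xs))


class TestPearsonScreen:
    def test_exact_linear(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0], "y": [2.0, 4.0, 6.0, 8.0]})
        res = pearson_screen(df)[0]
        assert res.r == pytest.approx(1.0)

    def test_hand_covariance_oracle(self):
        """r agrees with the brute-force covariance-formula computation."""
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        r_oracle = float(
            np.sum((x - x.mean()) * (y - y.mean()))
            / math.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        )
        res = pearson_screen(pd.DataFrame({"x": x, "y": y}))[0]
        assert res.r == pytest.approx(r_oracle, abs=1e-12)
        assert res.n == 5

    def test_independent_streams_near_zero(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame({"x": rng.normal(size=10_000), "y": rng.normal(size=10_000)})
        assert abs(pearson_screen(df)[0].r) < 0.05

    def test_pairwise_complete_and_flagging(self):
        df = pd.DataFrame({
            "a": [1.0, 2.0, np.nan, 4.0, 5.0],
            "b": [2.0, 1.0, 3.0, np.nan, 4.0],
            "c": [np.nan] * 4 + [1.0],
        })
        res = {(r.var_a, r.var_b): r for r in pearson_screen(df)}
        assert res[("a", "b")].n == 3
        assert res[("a", "c")].flagged

    def test_zero_variance_warns(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="zero variance"):
            res = pearson_screen(df)[0]
        assert math.isnan(res.r)


class TestCollinearityGate:
    def test_duplicate_column_fails(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        ok, pairs = collinearity_gate(pd.DataFrame({"a": x, "b": x}))
        assert not ok and pairs

    def test_orthogonal_design_passes(self):
        df = pd.DataFrame({
            "a": [1.0, 1.0, -1.0, -1.0],
            "b": [1.0, -1.0, 1.0, -1.0],
        })
        ok, pairs = collinearity_gate(df)
        assert ok and not pairs

    def test_strongly_correlated_pair_fails(self):
        rng = np.random.default_rng(123)
        x = rng.normal(size=1000)
        y = 0.9 * x + math.sqrt(1 - 0.81) * rng.normal(size=1000)
        ok, pairs = collinearity_gate(pd.DataFrame({"x": x, "y": y}))
        assert not ok
        assert pairs[0][2] == pytest.approx(0.9, abs=0.05)


class TestGaussianGlm:
    def test_exact_linear_fit(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        y = 1.0 + 2.0 * X["a"] - 3.0 * X["b"]
        fit = fit_gaussian_glm(y, X)
        assert fit.pseudo_r2 == pytest.approx(1.0, abs=1e-9)
        assert fit.lrt_p < 1e-12
        assert fit.estimates[1] == pytest.approx(2.0, abs=1e-9)
        assert fit.fit_class == "good"

    def test_normal_equations_oracle(self):
        """Coefficients equal the closed-form least-squares solution."""
        rng = np.random.default_rng(17)
        X = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"))
        y = rng.normal(size=10)
        fit = fit_gaussian_glm(y, X)
        design = np.column_stack([np.ones(10), X.to_numpy()])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        np.testing.assert_allclose(fit.estimates, beta, atol=1e-8)

    def test_rank_deficiency_names_alias(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=20)
        X = pd.DataFrame({"a": a, "b": 2.0 * a})
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_gaussian_glm(rng.normal(size=20), X)

    def test_lrt_invariant_to_predictor_rescaling(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(60, 2)), columns=["a", "b"])
        y = X["a"] + rng.normal(size=60)
        f1 = fit_gaussian_glm(y, X)
        X2 = X.copy()
        X2["a"] = 1000.0 * X2["a"] + 7.0
        f2 = fit_gaussian_glm(y, X2)
        assert f1.lrt_chi2 == pytest.approx(f2.lrt_chi2, rel=1e-8)
        assert f1.pseudo_r2 == pytest.approx(f2.pseudo_r2, rel=1e-8)

    def test_pseudo_r2_monotone_in_added_predictor(self):
        rng = np.random.default_rng(21)
        X = pd.DataFrame(rng.normal(size=(80, 3)), columns=list("abc"))
        y = X["a"] + rng.normal(size=80)
        f1 = fit_gaussian_glm(y, X[["a"]])
        f2 = fit_gaussian_glm(y, X[["a", "b"]])
        assert f2.pseudo_r2 >= f1.pseudo_r2 - 1e-12

    def test_listwise_deletion(self):
        rng = np.random.default_rng(31)
        X = pd.DataFrame({"a": rng.normal(size=30)})
        X.loc[3, "a"] = np.nan
        fit = fit_gaussian_glm(rng.normal(size=30), X)
        assert fit.n == 29


class TestClassifyFit:
    @pytest.mark.parametrize("r2,label", [
        (0.236, "good"),
        (0.05, "poor"),
        (0.15, "general"),
        (0.2, "good"),
        (0.1, "general"),
        (0.0999, "poor"),
    ])
    def test_thresholds(self, r2, label):
        assert classify_fit(r2) == label

    def test_domain(self):
        with pytest.raises(ValueError):
            classify_fit(1.5)


def _brute_force_u(a, b):
    """U as the count of (a_i, b_j) pairs with a_i > b_j (ties 1/2)."""
    u = 0.0
    for x in a:
        for y in b:
            u += 1.0 if x > y else (0.5 if x == y else 0.0)
    return u


class TestMannWhitney:
    def test_identical_groups(self):
        res = mann_whitney_z([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.value == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_fully_separated_groups(self):
        res = mann_whitney_z([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.u == 0.0

    def test_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(44)
        a = rng.normal(size=25)
        b = rng.normal(0.5, size=30)
        ours = mann_whitney_z(a, b)
        ref = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic",
            use_continuity=False,
        )
        assert ours.p == pytest.approx(float(ref.pvalue), rel=1e-9)

    def test_power_scaled_down(self):
        """Shifted normals (1 sd, n=200) are detected virtually always."""
        rng = np.random.default_rng(55)
        hits = 0
        for _ in range(20):
            a = rng.normal(size=200)
            b = rng.normal(1.0, size=200)
            hits += mann_whitney_z(a, b).p < 0.001
        assert hits >= 19

    def test_ties_against_enumeration(self):
        rng = np.random.default_rng(66)
        for _ in range(50):
            a = rng.integers(0, 4, size=rng.integers(2, 7)).astype(float)
            b = rng.integers(0, 4, size=rng.integers(2, 7)).astype(float)
            assert mann_whitney_z(a, b).u == pytest.approx(_brute_force_u(a, b))


class TestStudentT:
    def test_identical_groups(self):
        res = student_t([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res.value == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_hand_pooled_formula(self):
        """a=(1,2,3), b=(3,4,5): pooled sd 1, t = −2/(1·√(2/3)) = −2.449."""
        res = student_t([1.0, 2.0, 3.0], [3.0, 4.0, 5.0])
        assert res.statistic_label == "t"
        assert res.value == pytest.approx(-2.0 / math.sqrt(2.0 / 3.0), rel=1e-6)

    def test_type_i_error_scaled_down(self):
        rng = np.random.default_rng(77)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            a = rng.normal(size=50)
            b = rng.normal(size=50)
            res = student_t(a, b)
            rejections += res.p < 0.05
        assert 0.02 <= rejections / n_rep <= 0.09

    def test_fallback_on_heteroscedasticity(self):
        rng = np.random.default_rng(88)
        a = rng.normal(0, 1, size=60)
        b = rng.normal(0, 8, size=60)
        res = student_t(a, b)
        assert res.statistic_label == "Z"
        assert "fell back" in res.note
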
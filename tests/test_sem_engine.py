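"""CFA/SEM estimation: implied moments, discrepancies, SEs, fit indices."""

import numpy as np
import pytest

from pssem import sem_engine as se
from pssem.datagen import generate_linear_continuous
from pssem.ps_core import SampleMatrix, pearson_matrix
from pssem.sem_engine import (
    CFAModel,
    ParameterVector,
    chi_square,
    duplication_matrix,
    duplication_weight_ml,
    fit,
    fit_baseline,
    fit_indices,
    implied_sigma,
    parse_model,
    standard_errors,
    vech,
    weight_wls,
)
from pssem.simulation import design_model, design_sigma, population_ps_matrix


def _pv(model, lam_val, phi_val, theta_val):
    lam = np.where(model.loading_pattern, lam_val, 0.0)
    phi = np.full((model.m, model.m), phi_val)
    np.fill_diagonal(phi, 1.0)
    return ParameterVector(lam, phi, np.full(model.p, theta_val),
                           np.zeros((model.m, 0)), np.zeros((0, 0)))


class TestModelSyntax:
    def test_parse_and_counts(self):
        m = parse_model("""
            # measurement part
            F1 =~ y1 + y2 + y3
            F2 =~ y4 + y5 + y6
        """)
        assert m.items == [f"y{i}" for i in range(1, 7)]
        assert m.factors == ["F1", "F2"]
        assert m.t == 6 + 1 + 6      # loadings + correlation + residuals
        assert m.df == 21 - 13

    def test_roundtrip(self):
        text = "F1 =~ y1 + y2 + y3\nF2 =~ y4 + y5\nF1 ~ x1 + x2\nF2 ~ x1"
        m = parse_model(text)
        again = parse_model(m.to_syntax())
        assert again.items == m.items
        assert again.exog == ["x1", "x2"]
        np.testing.assert_array_equal(again.loading_pattern, m.loading_pattern)
        np.testing.assert_array_equal(again.structural_pattern,
                                      m.structural_pattern)

    @pytest.mark.parametrize("bad", [
        "y1 + y2",                      # no operator
        "F1 =~ y1 + 2bad",              # bad name
        "F9 ~ x1",                      # structural for undeclared factor
        "",                             # empty model
    ])
    def test_malformed_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_model(bad)

    def test_design_df_matches_counts(self, design_model):
        # 20 loadings + 6 correlations + 20 residuals = 46 free parameters
        assert design_model.t == 46
        assert design_model.df == 164


class TestImpliedSigma:
    def test_one_factor_closed_form(self):
        m = parse_model("F1 =~ y1 + y2")
        pv = _pv(m, 0.7, 0.0, 0.51)
        np.testing.assert_allclose(implied_sigma(m, pv),
                                   [[1.0, 0.49], [0.49, 1.0]])

    def test_design_structure(self, design_model):
        pv = _pv(design_model, 0.7, 0.3, 0.51)
        sig = implied_sigma(design_model, pv)
        assert sig[0, 1] == pytest.approx(0.49)
        assert sig[0, 5] == pytest.approx(0.7 * 0.3 * 0.7)
        np.testing.assert_allclose(np.diag(sig), 1.0)

    def test_zero_loadings_give_theta(self):
        m = parse_model("F1 =~ y1 + y2 + y3")
        pv = _pv(m, 0.0, 0.0, 0.4)
        np.testing.assert_allclose(implied_sigma(m, pv), 0.4 * np.eye(3))


class TestVechAndWeights:
    def test_vech_length_and_order(self):
        mat = np.array([[1.0, 4.0], [4.0, 2.0]])
        np.testing.assert_allclose(vech(mat), [1.0, 4.0, 2.0])
        assert vech(np.eye(5)).size == 15

    def test_duplication_identity(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(4, 4))
        sym = a + a.T
        d = duplication_matrix(4)
        np.testing.assert_allclose(d @ vech(sym), sym.flatten(order="F"))

    def test_normal_theory_weight_matches_ml_curvature(self, one_factor_model):
        """The quadratic form with W_ML^-1 reproduces F_ML near the optimum."""
        pv = _pv(one_factor_model, 0.8, 0.0, 0.36)
        sigma0 = implied_sigma(one_factor_model, pv)
        w_inv = duplication_weight_ml(sigma0)
        rng = np.random.default_rng(1)
        for _ in range(5):
            pert = rng.normal(scale=2e-3, size=sigma0.shape)
            s = sigma0 + pert + pert.T
            _, logdet_s = np.linalg.slogdet(s)
            f_ml, _ = se._ml_value_grad(sigma0, s, logdet_s,
                                        one_factor_model, pv, False)
            r = vech(s) - vech(sigma0)
            f_quad = float(r @ w_inv @ r)
            assert f_quad == pytest.approx(f_ml, rel=0.05, abs=1e-9)

    def test_adf_weight_matches_isserlis_for_normal_data(self):
        """For MVN data the ADF fourth-moment weight converges to the
        normal-theory form s_ik s_jl + s_il s_jk."""
        sigma = np.array([[1.0, 0.5], [0.5, 1.0]])
        x = generate_linear_continuous(sigma, 2 * 10**5, seed=3)
        w = weight_wls(x)
        s = np.cov(x.T, ddof=0)
        rows, cols = se._vech_indices(2)
        expect = np.empty_like(w)
        for a, (i, j) in enumerate(zip(rows, cols)):
            for b, (k, l) in enumerate(zip(rows, cols)):
                expect[a, b] = s[i, k] * s[j, l] + s[i, l] * s[j, k]
        np.testing.assert_allclose(w, expect, atol=0.05)

    def test_small_n_warns(self):
        rng = np.random.default_rng(4)
        with pytest.warns(UserWarning, match="ADF"):
            weight_wls(rng.normal(size=(8, 4)))


class TestFit:
    def test_perfect_fit_recovery(self, one_factor_model):
        pv = _pv(one_factor_model, 0.65, 0.0, 1.0 - 0.65**2)
        sigma0 = implied_sigma(one_factor_model, pv)
        for est in ("ml", "uls"):
            res = fit(one_factor_model, sigma0, n=500, estimator=est)
            assert res.converged
            assert res.T == pytest.approx(0.0, abs=1e-6)
            lams = [v for k, v in res.estimates.as_dict(one_factor_model).items()
                    if "=~" in k]
            assert np.allclose(lams, 0.65, atol=1e-4)

    def test_population_linear_recovery(self, design_model, design_sigma):
        res = fit(design_model, design_sigma, n=1000, estimator="ml")
        d = res.estimates.as_dict(design_model)
        lams = [v for k, v in d.items() if "=~" in k]
        phis = [v for k, v in d.items()
                if k.count("~") == 2 and k[0] == "F"]
        assert np.allclose(lams, 0.70, atol=1e-5)
        assert np.allclose(phis, 0.30, atol=1e-5)
        assert res.T < 1e-9

    def test_population_ps_recovery(self, design_model, design_sigma):
        """The population PS matrix is exactly representable: loadings
        sqrt(asin(.49)/pi + .5) ~ 0.8143, correlations ~ 0.8250."""
        ps = population_ps_matrix(design_sigma)
        res = fit(design_model, ps, n=1000, estimator="ml")
        d = res.estimates.as_dict(design_model)
        lams = [v for k, v in d.items() if "=~" in k]
        phis = [v for k, v in d.items() if k.count("~") == 2 and k[0] == "F"]
        assert np.allclose(lams, 0.81425, atol=1e-3)
        assert np.allclose(phis, 0.82498, atol=1e-3)
        assert res.T == pytest.approx(0.0, abs=1e-8)

    def test_ml_equals_mlr_point_estimates(self, one_factor_model, rng):
        pv = _pv(one_factor_model, 0.7, 0.0, 0.51)
        data = generate_linear_continuous(
            implied_sigma(one_factor_model, pv), 500, rng)
        s = pearson_matrix(data).to_correlation()
        est_ml = fit(one_factor_model, s, estimator="ml").estimates
        est_mlr = fit(one_factor_model, s, estimator="mlr").estimates
        np.testing.assert_allclose(est_ml.lambdas, est_mlr.lambdas, atol=1e-8)

    def test_analytic_gradient_matches_numerical(self, one_factor_model):
        pv = _pv(one_factor_model, 0.7, 0.0, 0.51)
        s_arr = implied_sigma(one_factor_model, pv) + 0.03 * np.eye(4)
        for base in ("ml", "uls"):
            obj, kinds, analytic = se._make_objective(one_factor_model, base,
                                                      s_arr, None)
            assert analytic
            u = np.concatenate([np.full(4, 0.6), np.log(np.full(4, 0.4))])
            _, g = obj(u)
            num = np.empty_like(u)
            h = 1e-6
            for j in range(u.size):
                up, dn = u.copy(), u.copy()
                up[j] += h
                dn[j] -= h
                num[j] = (obj(up, False)[0] - obj(dn, False)[0]) / (2 * h)
            np.testing.assert_allclose(g, num, rtol=1e-4, atol=1e-7)

    def test_brute_force_oracle_small_model(self):
        """A dense multi-start/grid search of the same ML discrepancy lands
        on the optimizer's solution for a tiny one-factor model."""
        m = parse_model("F1 =~ y1 + y2 + y3")
        s_arr = np.array([[1.00, 0.42, 0.30],
                          [0.42, 1.00, 0.35],
                          [0.30, 0.35, 1.00]])
        res = fit(m, s_arr, n=200, estimator="ml")
        _, logdet_s = np.linalg.slogdet(s_arr)

        def f(lams, thetas):
            pv = ParameterVector(lams.reshape(3, 1), np.eye(1), thetas,
                                 np.zeros((1, 0)), np.zeros((0, 0)))
            val, _ = se._ml_value_grad(implied_sigma(m, pv), s_arr, logdet_s,
                                       m, pv, False)
            return val

        grid = np.linspace(0.05, 0.95, 19)
        best, best_val = None, np.inf
        for l1 in grid:
            for l2 in grid:
                for l3 in grid:
                    lams = np.array([l1, l2, l3])
                    thetas = np.clip(1.0 - lams**2, 0.05, None)
                    val = f(lams, thetas)
                    if val < best_val:
                        best, best_val = lams.copy(), val
        # refine the winning grid point with coordinate descent
        for _ in range(200):
            for j in range(3):
                for step in (0.01, -0.01, 0.001, -0.001):
                    cand = best.copy()
                    cand[j] += step
                    th = np.clip(1.0 - cand**2, 1e-3, None)
                    if f(cand, th) < best_val:
                        best, best_val = cand, f(cand, th)
        fitted = res.estimates.lambdas[:, 0]
        np.testing.assert_allclose(np.abs(fitted), np.abs(best), atol=1e-3)

    def test_structural_model_population_recovery(self):
        m = parse_model("F1 =~ y1 + y2 + y3\nF1 ~ x1")
        lam = np.array([[0.8], [0.7], [0.6]])
        gam = np.array([[0.5]])
        phi_x = np.array([[1.5]])
        thetas = np.array([0.3, 0.4, 0.5])
        pv0 = ParameterVector(lam, np.eye(1), thetas, gam, phi_x)
        sigma0 = implied_sigma(m, pv0)
        assert sigma0.shape == (4, 4)
        res = fit(m, sigma0, n=500, estimator="ml")
        assert res.converged
        assert res.T == pytest.approx(0.0, abs=1e-7)
        np.testing.assert_allclose(res.estimates.lambdas, lam, atol=1e-3)
        np.testing.assert_allclose(res.estimates.gammas, gam, atol=1e-3)

    def test_wrong_dimension_rejected(self, one_factor_model):
        with pytest.raises(ValueError, match="does not match"):
            fit(one_factor_model, np.eye(3), n=100)

    def test_unknown_estimator(self, one_factor_model):
        with pytest.raises(ValueError, match="unknown estimator"):
            fit(one_factor_model, np.eye(4), n=100, estimator="gls")


@pytest.fixture(scope="module")
def fitted(one_factor_model):
    pv = _pv(one_factor_model, 0.7, 0.0, 0.51)
    sigma0 = implied_sigma(one_factor_model, pv)
    out = {}
    for n in (400, 1600, 100000):
        data = generate_linear_continuous(sigma0, n, seed=n)
        s = pearson_matrix(data)
        res = fit(one_factor_model, s, estimator="ml")
        standard_errors(res, s)
        out[n] = (res, s, data)
    return out


class TestStandardErrors:
    def test_all_positive(self, fitted):
        res, _, _ = fitted[400]
        assert all(v > 0 for v in res.se.values())

    def test_inverse_sqrt_n_scaling(self, fitted):
        se400 = np.array(list(fitted[400][0].se.values()))
        se1600 = np.array(list(fitted[1600][0].se.values()))
        ratio = se400 / se1600
        assert np.allclose(ratio, 2.0, atol=0.35)

    def test_ml_and_mlr_agree_for_normal_data(self, fitted, one_factor_model):
        res_ml, s, data = fitted[100000]
        res_mlr = fit(one_factor_model, s, estimator="mlr")
        standard_errors(res_mlr, s, raw_data=data)
        a = np.array(list(res_ml.se.values()))
        b = np.array(list(res_mlr.se.values()))
        np.testing.assert_allclose(a, b, rtol=0.05)


class TestChiSquareAndIndices:
    def test_scaling_and_uls_flag(self):
        chi2, ok = chi_square(0.2, 101, "ml")
        assert chi2 == pytest.approx(20.0)
        assert ok
        _, ok_uls = chi_square(0.2, 101, "uls")
        assert not ok_uls

    def test_perfect_fit_chi2_zero(self):
        assert chi_square(0.0, 500)[0] == 0.0

    def test_chi2_mean_near_df_for_true_model(self, design_model,
                                              design_sigma):
        rng = np.random.default_rng(12)
        chis = []
        for _ in range(30):
            data = generate_linear_continuous(design_sigma, 400, rng)
            s = pearson_matrix(data).to_correlation()
            chis.append(fit(design_model, s, estimator="ml").chi2)
        # chi2_164 has mean 164 and SD ~18; 30 reps give SE ~ 3.3
        assert np.mean(chis) == pytest.approx(164, abs=12)

    def test_rmsea_arithmetic_example(self):
        # chi2(22) = 165.22 at n = 973 sits right at the 0.08 cutoff
        cfi, rmsea = fit_indices(165.22, 22, 3000.0, 28, 973)
        assert rmsea == pytest.approx(0.082, abs=5e-4)

    def test_saturated_fit(self):
        cfi, rmsea = fit_indices(22.0, 22, 500.0, 28, 400)
        assert cfi == 1.0
        assert rmsea == 0.0

    def test_cfi_clipped(self):
        cfi, _ = fit_indices(100.0, 22, 60.0, 28, 400)
        assert 0.0 <= cfi <= 1.0

    def test_bad_df_rejected(self):
        with pytest.raises(ValueError):
            fit_indices(10.0, 0, 50.0, 28, 100)

    def test_ml_baseline_closed_form(self, rng):
        data = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], size=300)
        s = pearson_matrix(data)
        chi2_b, df_b = fit_baseline(s, estimator="ml")
        r = s.to_correlation().values[0, 1]
        assert df_b == 1
        assert chi2_b == pytest.approx(-(300 - 1) * np.log(1 - r**2), rel=1e-9)

    def test_uls_baseline_zeroes_covariances(self, rng):
        data = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], size=300)
        s = pearson_matrix(data)
        chi2_b, _ = fit_baseline(s, estimator="uls")
        r01 = s.values[0, 1]
        assert chi2_b == pytest.approx((300 - 1) * r01**2, rel=1e-9)


class TestFitResultSerialization:
    def test_json_fields(self, one_factor_model):
        pv = _pv(one_factor_model, 0.7, 0.0, 0.51)
        res = fit(one_factor_model, implied_sigma(one_factor_model, pv),
                  n=300, estimator="ml")
        import json
        blob = json.loads(res.to_json())
        assert blob["converged"] is True
        assert blob["df"] == one_factor_model.df
        assert "F1=~y1" in blob["estimates"]
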
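"""Path-model specification, FIML likelihood, estimation and inference."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from hfpmediate.fiml import (FixedLikelihood, ObjectiveWrapper,
                             Parameterization, SaturatedLikelihood, mvn_mle)
from hfpmediate.pathmodel import PathModel, wald_tests
from hfpmediate.pathspec import PathModelSpec, build_model_spec, parse_model_syntax

from conftest import TINY_TRUTH, make_tiny_data

MEDIATORS = ["crop_richness", "garden_practices", "n_poultry", "n_eggs",
             "fg_knowledge", "dd_knowledge"]


class TestSpec:
    def test_default_seven_mediator_structure(self):
        spec = build_model_spec(MEDIATORS, "dds_mean", ["dds_baseline"],
                                treatment="arm", market="market_score")
        eqs = spec.equations
        # 7 a-paths: treatment into each mediator and the market score
        assert all("arm" in eqs[m] for m in MEDIATORS + ["market_score"])
        # 7 b-paths (6 mediators + market -> outcome) and the direct path
        assert all(m in eqs["dds_mean"] for m in MEDIATORS + ["market_score"])
        assert "arm" in eqs["dds_mean"]
        # 6 d-paths into the market score
        assert all(m in eqs["market_score"] for m in MEDIATORS)
        assert spec.residual_blocks == [
            ["crop_richness", "garden_practices", "n_poultry", "n_eggs"],
            ["fg_knowledge", "dd_knowledge"],
        ]

    def test_empty_mediator_list_reduces_to_regression(self):
        spec = build_model_spec([], "y", ["x"], treatment="t")
        assert spec.equations == {"y": ["t", "x"]}
        assert spec.endogenous == ["y"]

    def test_residual_block_of_four_frees_six_covariances(self):
        spec = build_model_spec(MEDIATORS, "y", [], treatment="t",
                                residual_blocks=[MEDIATORS[:4]])
        # block of 4 -> 4 variances + C(4,2)=6 covariances
        k = spec.n_free_parameters("fixed")
        singles = PathModelSpec(spec.equations, residual_blocks=[])
        assert k - singles.n_free_parameters("fixed") == 6

    def test_cyclic_specification_errors(self):
        with pytest.raises(ValueError, match="cyclic"):
            PathModelSpec({"a": ["b"], "b": ["a"]})

    def test_syntax_parser(self):
        spec = parse_model_syntax("""
            y ~ t + m1 + m2
            m1 ~ t
            m2 ~ t
            m1 ~~ m2
        """)
        assert spec.equations["y"] == ["t", "m1", "m2"]
        assert spec.exogenous == ["t"]
        assert spec.residual_blocks == [["m1", "m2"]]


class TestImpliedMoments:
    def test_intercept_only_single_variable(self):
        spec = PathModelSpec({"y": []})
        param = Parameterization(spec, "fixed")
        theta = param.pack(np.array([2.0]), np.zeros((1, 1)), np.zeros((1, 0)),
                           np.array([[1.0]]))
        (a0, Pi, S), _ = param.moments(theta)
        assert a0[0] == pytest.approx(2.0)
        assert S[0, 0] == pytest.approx(1.0)

    def test_intercept_shifts_mean_only(self, tiny_spec):
        param = Parameterization(tiny_spec, "fixed")
        rng = np.random.default_rng(0)
        theta = rng.normal(0, 0.3, param.n_params)
        (a0, Pi, S), _ = param.moments(theta)
        theta2 = theta.copy()
        theta2[1] += 0.7  # an alpha entry
        (a02, Pi2, S2), _ = param.moments(theta2)
        assert not np.allclose(a0, a02)
        np.testing.assert_allclose(Pi, Pi2)
        np.testing.assert_allclose(S, S2)

    def test_simulation_oracle(self, tiny_spec):
        """Empirical moments of structural-equation draws match mu, Sigma."""
        param = Parameterization(tiny_spec, "fixed")
        rng = np.random.default_rng(2)
        theta = rng.normal(0, 0.3, param.n_params)
        st = param.unpack(theta)
        (a0, Pi, S), _ = param.moments(theta)
        n = 1_000_000
        X = np.column_stack([rng.binomial(1, 0.5, n), rng.normal(size=n)])
        Z = rng.multivariate_normal(np.zeros(4), st["Psi"], size=n,
                                    method="cholesky")
        eta = np.empty((n, 4))
        base = st["alpha"] + X @ st["Gamma"].T + Z
        for j in range(4):
            eta[:, j] = base[:, j] + eta[:, :j] @ st["B"][j, :j]
        mu_emp = eta.mean(axis=0) - Pi @ X.mean(axis=0)
        resid = eta - X @ Pi.T
        np.testing.assert_allclose(mu_emp, a0, rtol=0.01, atol=0.01)
        np.testing.assert_allclose(np.cov(resid.T), S, rtol=0.01, atol=0.01)


class TestLoglik:
    def test_univariate_closed_form_at_mle(self):
        rng = np.random.default_rng(3)
        y = rng.normal(2, 1.5, size=50)[:, None]
        like = FixedLikelihood(y, np.empty((50, 0)))
        mu, var = y.mean(), y.var()
        ll = like.loglik(np.array([mu]), np.empty((1, 0)), np.array([[var]]))
        closed = -0.5 * 50 * (np.log(2 * np.pi * var) + 1)
        assert ll == pytest.approx(closed, rel=1e-12)

    def test_casewise_brute_force_with_holes(self):
        # 5-row toy: FIML loglik equals summed marginal normal densities
        mu = np.array([1.0, -0.5, 0.3])
        Sig = np.array([[1.0, 0.3, 0.1], [0.3, 0.8, -0.2], [0.1, -0.2, 1.5]])
        Z = np.array([
            [0.5, np.nan, 1.0],
            [np.nan, 0.2, np.nan],
            [1.5, -1.0, 0.0],
            [np.nan, np.nan, 2.0],
            [0.1, 0.4, np.nan],
        ])
        like = SaturatedLikelihood(Z)
        ll = like.loglik(mu, Sig)
        brute = 0.0
        for row in Z:
            o = ~np.isnan(row)
            brute += stats.multivariate_normal.logpdf(
                row[o], mu[o], Sig[np.ix_(o, o)]
            )
        assert ll == pytest.approx(brute, rel=1e-12)

    def test_duplicated_data_doubles_loglik(self):
        rng = np.random.default_rng(4)
        Z = rng.normal(size=(20, 2))
        Z[rng.random((20, 2)) < 0.2] = np.nan
        Z = Z[~np.isnan(Z).all(axis=1)]
        mu, Sig = np.zeros(2), np.eye(2)
        l1 = SaturatedLikelihood(Z).loglik(mu, Sig)
        l2 = SaturatedLikelihood(np.vstack([Z, Z])).loglik(mu, Sig)
        assert l2 == pytest.approx(2 * l1, rel=1e-12)

    def test_row_with_nothing_observed_errors(self):
        Z = np.array([[1.0, 2.0], [np.nan, np.nan]])
        with pytest.raises(ValueError, match="no observed"):
            SaturatedLikelihood(Z)

    def test_pattern_grouping_equals_casewise(self, tiny_spec):
        """Grouped evaluation is a speed contract, not a different quantity."""
        df = make_tiny_data(80, seed=9, n_clusters=8, holes=True)
        param = Parameterization(tiny_spec, "fixed")
        like = FixedLikelihood(df[tiny_spec.endogenous].to_numpy(),
                               df[tiny_spec.exogenous].to_numpy())
        theta = np.random.default_rng(1).normal(0, 0.2, param.n_params)
        (a0, Pi, S), _ = param.moments(theta)
        ll = like.loglik(a0, Pi, S)
        brute = 0.0
        for _, row in df.iterrows():
            y = row[tiny_spec.endogenous].to_numpy(float)
            x = row[tiny_spec.exogenous].to_numpy(float)
            o = ~np.isnan(y)
            brute += stats.multivariate_normal.logpdf(
                y[o], (a0 + Pi @ x)[o], S[np.ix_(o, o)]
            )
        assert ll == pytest.approx(brute, rel=1e-10)


class TestGradients:
    @pytest.mark.parametrize("mode", ["fixed", "saturated"])
    def test_analytic_gradient_matches_finite_differences(self, tiny_spec, mode):
        df = make_tiny_data(60, seed=7, n_clusters=6, holes=True)
        param = Parameterization(tiny_spec, mode)
        if mode == "fixed":
            like = FixedLikelihood(df[tiny_spec.endogenous].to_numpy(),
                                   df[tiny_spec.exogenous].to_numpy())
        else:
            df.loc[3:8, "x1"] = np.nan
            like = SaturatedLikelihood(
                df[tiny_spec.exogenous + tiny_spec.endogenous].to_numpy()
            )
        obj = ObjectiveWrapper(param, like)
        theta = np.random.default_rng(0).normal(0, 0.3, param.n_params)
        _, g = obj.value_and_grad(theta)
        h = 1e-6
        for i in range(0, param.n_params, 3):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h
            tm[i] -= h
            fd = (obj.value_and_grad(tp)[0] - obj.value_and_grad(tm)[0]) / (2 * h)
            assert g[i] == pytest.approx(fd, rel=5e-5, abs=1e-7)

    def test_rowwise_scores_sum_to_gradient(self, tiny_spec):
        df = make_tiny_data(60, seed=7, n_clusters=6, holes=True)
        param = Parameterization(tiny_spec, "fixed")
        like = FixedLikelihood(df[tiny_spec.endogenous].to_numpy(),
                               df[tiny_spec.exogenous].to_numpy())
        obj = ObjectiveWrapper(param, like)
        theta = np.random.default_rng(0).normal(0, 0.3, param.n_params)
        _, g = obj.value_and_grad(theta)
        mom, _ = param.moments(theta)
        _, G = like.loglik(*mom, rowwise=True)
        s = G @ param.jacobian(theta)
        np.testing.assert_allclose(s.sum(axis=0), -g, atol=1e-9)


class TestFit:
    def test_complete_data_equals_equationwise_ols(self, tiny_data, tiny_spec,
                                                   tiny_fit):
        for dep, regs in tiny_spec.equations.items():
            D = sm.add_constant(tiny_data[regs])
            ols = sm.OLS(tiny_data[dep], D).fit()
            est = np.array([tiny_fit.params[f"{dep}~1"]]
                           + [tiny_fit.params[f"{dep}~{r}"] for r in regs])
            np.testing.assert_allclose(est, ols.params.to_numpy(), atol=1e-6)

    def test_near_noiseless_mediators_recovered_exactly(self):
        # noiseless limit: residual sd 1e-4 on the mediators
        rng = np.random.default_rng(5)
        n = 150
        T = rng.binomial(1, 0.5, n).astype(float)
        m1 = 1.0 + 0.5 * T + 1e-4 * rng.normal(size=n)
        y = 2.0 + 0.3 * T + 0.4 * m1 + rng.normal(size=n)
        df = pd.DataFrame({"t": T, "m1": m1, "y": y})
        spec = build_model_spec(["m1"], "y", [], treatment="t")
        res = PathModel(df, spec).fit()
        assert res.params["m1~t"] == pytest.approx(0.5, abs=1e-4)

    def test_mcar_estimates_near_complete_estimates(self, tiny_spec):
        df = make_tiny_data(400, seed=8, n_clusters=40)
        full = PathModel(df, tiny_spec, cluster="cl").fit()
        rng = np.random.default_rng(1)
        df2 = df.copy()
        for c in ["m1", "m2", "mkt"]:
            df2.loc[rng.random(len(df2)) < 0.2, c] = np.nan
        holed = PathModel(df2, tiny_spec, cluster="cl").fit()
        se = full.bse("naive")
        for lab in ["m1~t", "m2~t", "y~m1", "y~mkt", "y~t", "mkt~m1"]:
            assert abs(full.params[lab] - holed.params[lab]) < 3 * se[lab] + 0.05

    def test_modes_agree_on_complete_data(self, tiny_data, tiny_spec, tiny_fit):
        sat = PathModel(tiny_data, tiny_spec, cluster="cl", mode="saturated").fit()
        diff = np.abs(sat.params[tiny_fit.params.index] - tiny_fit.params).max()
        assert diff < 1e-4

    def test_invariant_to_row_order_and_cluster_labels(self, tiny_data,
                                                       tiny_spec, tiny_fit):
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(tiny_data))
        df = tiny_data.iloc[perm].reset_index(drop=True)
        df["cl"] = df["cl"].map(lambda c: f"settlement_{c}")
        res = PathModel(df, tiny_spec, cluster="cl").fit()
        np.testing.assert_allclose(res.params, tiny_fit.params, atol=1e-6)
        np.testing.assert_allclose(res.vcov("cluster"),
                                   tiny_fit.vcov("cluster"), atol=1e-6)

    def test_loglik_at_mle_beats_start(self, tiny_data, tiny_spec, tiny_fit):
        model = PathModel(tiny_data, tiny_spec)
        assert tiny_fit.loglik >= model.loglik(model.start_values()) - 1e-9
        assert tiny_fit.grad_norm < 1e-5


class TestClusterRobust:
    def test_iid_limit_equals_perrow_sandwich(self, tiny_spec):
        """Every row its own cluster == HC sandwich from per-row numeric scores."""
        df = make_tiny_data(80, seed=2, n_clusters=80)
        res = PathModel(df, tiny_spec, cluster="cl").fit()
        model = PathModel(df, tiny_spec)  # no clusters: rows are the units
        res2 = model.fit()
        V_rows = res2.vcov("cluster")
        np.testing.assert_allclose(res.vcov("cluster"), V_rows, rtol=1e-5,
                                   atol=1e-10)
        # independent oracle: numeric per-row scores
        like = model.like
        param = model.param

        def row_ll(theta, i):
            mom, _ = param.moments(theta)
            a0, Pi, S = mom
            y = like.Y[i]
            x = like.X[i]
            o = ~np.isnan(y)
            return stats.multivariate_normal.logpdf(
                y[o], (a0 + Pi @ x)[o], S[np.ix_(o, o)]
            )

        h = 1e-5
        n_par = param.n_params
        S_num = np.zeros((len(df), n_par))
        th = res2.theta
        for k in range(n_par):
            tp, tm = th.copy(), th.copy()
            tp[k] += h
            tm[k] -= h
            for i in range(len(df)):
                S_num[i, k] = (row_ll(tp, i) - row_ll(tm, i)) / (2 * h)
        B = S_num.T @ S_num
        Ainv = np.linalg.inv(res2.hessian())
        V_oracle = Ainv @ B @ Ainv
        np.testing.assert_allclose(V_rows, V_oracle, rtol=5e-3, atol=1e-8)

    def test_symmetric_psd(self, tiny_fit):
        V = tiny_fit.vcov("cluster")
        np.testing.assert_allclose(V, V.T, atol=1e-12)
        assert np.linalg.eigvalsh(V).min() > -1e-10

    def test_duplicating_clusters_halves_vcov(self, tiny_data, tiny_spec, tiny_fit):
        df2 = pd.concat([
            tiny_data,
            tiny_data.assign(cl=tiny_data["cl"].astype(str) + "_copy"),
        ], ignore_index=True)
        res2 = PathModel(df2, tiny_spec, cluster="cl").fit(start=tiny_fit.theta)
        V1 = tiny_fit.vcov("cluster")
        V2 = res2.vcov("cluster")
        np.testing.assert_allclose(V2, V1 / 2, rtol=1e-3, atol=1e-10)


class TestWald:
    def test_scalar_examples(self):
        z, p = wald_tests([0.0], [1.0])
        assert p[0] == pytest.approx(1.0)
        z, p = wald_tests([1.959964 * 2.0], [4.0])
        assert p[0] == pytest.approx(0.05, abs=1e-6)

    def test_vector_matches_scalar(self):
        est = np.array([0.5, -1.2, 2.0])
        var = np.array([0.04, 0.25, 1.0])
        z, p = wald_tests(est, var)
        for i in range(3):
            zi, pi = wald_tests([est[i]], [var[i]])
            assert z[i] == pytest.approx(zi[0]) and p[i] == pytest.approx(pi[0])

    def test_zero_se_flagged(self):
        with pytest.warns(UserWarning, match="zero standard error"):
            z, p = wald_tests([1.0], [0.0])
        assert np.isnan(p[0])


class TestFitIndices:
    def test_saturated_model(self, tiny_fit):
        # the tiny spec is saturated (df = 0): chi2 = 0, CFI = 1, RMSEA = 0
        fi = tiny_fit.fit_indices()
        assert fi["df"] == 0
        assert fi["chi2"] == pytest.approx(0.0, abs=1e-6)
        assert fi["cfi"] == 1.0
        assert fi["rmsea"] == 0.0
        assert np.isnan(fi["tli"])

    def test_independence_model_chi2_closed_form(self):
        rng = np.random.default_rng(6)
        n, r = 600, 0.55
        Z = rng.multivariate_normal([0, 0], [[1, r], [r, 1]], size=n)
        df = pd.DataFrame(Z, columns=["y1", "y2"])
        spec = PathModelSpec({"y1": [], "y2": []})  # independence
        res = PathModel(df, spec).fit()
        fi = res.fit_indices()
        r_emp = np.corrcoef(Z.T)[0, 1]
        expected = -n * np.log(1 - r_emp ** 2)
        assert fi["df"] == 1
        assert fi["chi2"] == pytest.approx(expected, abs=1e-3)
        # the independence model IS the baseline here
        assert fi["chi2_baseline"] == pytest.approx(fi["chi2"], abs=1e-3)
        assert fi["rmsea"] == pytest.approx(
            np.sqrt((fi["chi2"] - 1) / n), rel=1e-6)

    def test_em_mvn_matches_complete_closed_form(self):
        rng = np.random.default_rng(8)
        Z = rng.multivariate_normal([1, -1, 0], np.diag([1, 2, 0.5]), size=120)
        Zh = Z.copy()
        Zh[rng.random(Zh.shape) < 0.15] = np.nan
        Zh = Zh[~np.isnan(Zh).all(axis=1)]
        mu, Sig, ll = mvn_mle(Zh)
        # EM solution is a stationary point: gradient of the observed-data
        # loglik wrt (mu, Sigma) vanishes
        like = SaturatedLikelihood(Zh)
        _, g_mu, g_Sig = like.loglik(mu, Sig, grad=True)
        assert np.abs(g_mu).max() < 1e-4
        assert np.abs(g_Sig).max() < 1e-4


class TestStandardized:
    def test_prescaled_variables_unchanged(self):
        rng = np.random.default_rng(10)
        n = 5000
        t = rng.normal(size=n)
        y = 0.5 * t + rng.normal(size=n) * np.sqrt(0.75)
        df = pd.DataFrame({"t": t / t.std(), "y": y / y.std()})
        spec = build_model_spec([], "y", [], treatment="t")
        res = PathModel(df, spec).fit()
        std = res.standardized_params()
        assert std["y~t"] == pytest.approx(res.params["y~t"], rel=0.02)

    def test_scale_invariance(self, tiny_data, tiny_spec, tiny_fit):
        df = tiny_data.copy()
        df["m1"] = df["m1"] * 10
        res = PathModel(df, tiny_spec).fit()
        s1 = tiny_fit.standardized_params()
        s2 = res.standardized_params()
        assert s2["y~m1"] == pytest.approx(s1["y~m1"], abs=1e-6)

    def test_formula_oracle(self, tiny_fit):
        _, Sigma = tiny_fit.implied_moments()
        sd = np.sqrt(np.diag(Sigma))
        names = list(Sigma.index)
        got = tiny_fit.standardized_params()["y~m1"]
        exp = (tiny_fit.params["y~m1"] * sd[names.index("m1")]
               / sd[names.index("y")])
        assert got == pytest.approx(exp, rel=1e-10)
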
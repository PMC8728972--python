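"""Mixed model: design assembly, covariance, GLS, likelihood, ML fit."""

from dataclasses import replace

import numpy as np
import pytest
import scipy.linalg as sla
from scipy import stats

from gdmlda.cohort import CohortTable, SchemaError
from gdmlda.mlmm import (
    MultivariateLongitudinalModel,
    ModelSpec,
    RankDeficiencyError,
    build_design,
    gls_beta,
    log_likelihood,
    marginal_covariance,
    params_to_theta,
    theta_to_params,
)
from gdmlda.simulate import generate_from_model

from conftest import example_truth


class TestBuildDesign:
    def test_shapes_default_spec(self, small_cohort):
        d = build_design(small_cohort)
        n = small_cohort.n_subjects
        assert d.Y.shape == (n, 8)
        assert d.X.shape == (n, 8, 28)
        assert d.Z.shape == (8, 4)
        # per-biomarker block structure: marker m's columns live only in
        # its own two rows
        for jm in range(4):
            cols = slice(jm * 7, (jm + 1) * 7)
            other_rows = [r for r in range(8) if r // 2 != jm]
            assert np.all(d.X[:, other_rows, cols] == 0)

    def test_single_marker_q2(self, small_cohort):
        d = build_design(small_cohort, ModelSpec(response_markers=("fbs",)))
        assert d.Y.shape[1] == 2
        assert d.X.shape[2] == 7

    def test_row_order_invariance(self, small_cohort):
        d1 = build_design(small_cohort)
        shuffled = small_cohort.data.sample(frac=1.0, random_state=0)
        d2 = build_design(CohortTable(shuffled))
        np.testing.assert_array_equal(d1.Y, d2.Y)
        np.testing.assert_array_equal(d1.X, d2.X)

    def test_group_coded_as_indicator(self, small_cohort):
        d = build_design(small_cohort)
        gcols = d.group_column_indices()
        vals = np.unique(d.X[:, :, gcols])
        assert set(vals) <= {0.0, 1.0}
        assert set(np.unique(d.groups)) <= {1, 2}

    def test_missing_covariate_errors(self, small_cohort):
        df = small_cohort.data.drop(columns=["sbp"])
        with pytest.raises(SchemaError, match="sbp"):
            build_design(CohortTable(df))


class TestMarginalCovariance:
    def test_zero_D_gives_diagonal(self):
        V = marginal_covariance(np.zeros((4, 4)), np.full(4, 2.5))
        np.testing.assert_allclose(V, 2.5 * np.eye(8))

    def test_compound_symmetry_single_marker(self):
        d, s2 = 0.7, 1.3
        V = marginal_covariance(np.array([[d]]), np.array([s2]))
        np.testing.assert_allclose(V, [[d + s2, d], [d, d + s2]])

    def test_matches_monte_carlo_covariance(self):
        truth = example_truth()
        t = generate_from_model(truth, 50000, 0.2, seed=21)
        d = build_design(t, truth.spec)
        R = d.Y - d.X @ truth.beta
        emp = R.T @ R / R.shape[0]
        V = marginal_covariance(truth.D, truth.omega_variances)
        assert np.linalg.norm(emp - V) / np.linalg.norm(V) < 0.05

    def test_theta_round_trip(self):
        rng = np.random.default_rng(3)
        A = rng.standard_normal((4, 4))
        D = A @ A.T + np.eye(4)
        omega = np.abs(rng.standard_normal(4)) + 0.5
        D2, om2 = theta_to_params(params_to_theta(D, omega), 4)
        np.testing.assert_allclose(D2, D, atol=1e-7)
        np.testing.assert_allclose(om2, omega)


class TestGlsAndLikelihood:
    def test_identity_V_reduces_to_ols(self, small_cohort):
        d = build_design(small_cohort)
        beta = gls_beta(np.eye(8), d)
        Xs = d.X.reshape(-1, 28)
        ols, *_ = np.linalg.lstsq(Xs, d.Y.reshape(-1), rcond=None)
        np.testing.assert_allclose(beta, ols, atol=1e-8)

    def test_scaling_V_leaves_beta(self, small_cohort):
        d = build_design(small_cohort)
        truth = example_truth()
        V = marginal_covariance(truth.D, truth.omega_variances)
        b1 = gls_beta(V, d)
        b2 = gls_beta(7.3 * V, d)
        np.testing.assert_allclose(b1, b2, rtol=1e-9)

    def test_duplicate_column_raises_rank_error(self, small_cohort):
        df = small_cohort.data.copy()
        df["sbp"] = df["bmi"]  # exact duplicate covariate
        with pytest.raises(RankDeficiencyError, match="sbp|bmi"):
            MultivariateLongitudinalModel(CohortTable(df))

    def test_loglik_matches_dense_mvn_oracle(self):
        truth = example_truth()
        t = generate_from_model(truth, 40, 0.3, seed=5)
        d = build_design(t, truth.spec)
        ll = log_likelihood(truth.beta, truth.D, truth.omega_variances, d)
        V = marginal_covariance(truth.D, truth.omega_variances)
        oracle = sum(
            stats.multivariate_normal.logpdf(s.y, s.X @ truth.beta, V)
            for s in d
        )
        assert ll == pytest.approx(oracle, abs=1e-8)

    def test_translation_invariance(self):
        truth = example_truth()
        t = generate_from_model(truth, 30, 0.3, seed=6)
        d = build_design(t, truth.spec)
        ll = log_likelihood(truth.beta, truth.D, truth.omega_variances, d)
        c = 3.7
        beta_shift = truth.beta.copy()
        for jm in range(4):
            beta_shift[jm * 7] += c  # per-marker intercepts
        d2 = build_design(t, truth.spec)
        d2.Y = d.Y + c
        ll2 = log_likelihood(beta_shift, truth.D, truth.omega_variances, d2)
        assert ll2 == pytest.approx(ll, abs=1e-8)

    def test_closed_form_at_zero_residuals(self):
        truth = example_truth(ModelSpec(response_markers=("hb",)))
        truth = replace(
            truth, D=np.zeros((1, 1)), omega_variances=np.array([1e-30])
        )
        t = generate_from_model(truth, 1, 0.0, seed=7)
        d = build_design(t, truth.spec)
        ll = log_likelihood(truth.beta, np.zeros((1, 1)), np.array([1.0]), d)
        # q = 2, V = I, zero residuals: ll = -(q/2) log 2pi
        assert ll == pytest.approx(-np.log(2 * np.pi), abs=1e-8)


class TestFit:
    def test_recovery_with_zero_random_effects(self):
        spec = ModelSpec()
        truth = replace(
            example_truth(spec),
            D=np.zeros((4, 4)),
            omega_variances=np.array([0.9, 9.0, 130.0, 0.2]),
        )
        t = generate_from_model(truth, 2000, 0.3, seed=10)
        res = MultivariateLongitudinalModel(t, spec).fit()
        assert res.converged
        se = res.bse.to_numpy()
        assert np.all(np.abs(res.beta.to_numpy() - truth.beta) < 3.5 * se)
        # D collapses: largest eigenvalue under 5% of the smallest noise var
        rel = np.linalg.eigvalsh(res.D.to_numpy()).max()
        assert rel < 0.05 * truth.omega_variances.min() or rel < 0.05 * np.max(
            truth.omega_variances
        )

    def test_stationarity_of_refit(self, small_cohort):
        model = MultivariateLongitudinalModel(small_cohort)
        res = model.fit()
        res2 = model.fit(start=res)
        assert abs(res2.loglik - res.loglik) < 1e-6

    def test_affine_rescaling_equivariance(self):
        """Rescaling one biomarker by a shifts loglik by the Jacobian
        -n t log a and scales its coefficients by a."""
        truth = example_truth()
        t = generate_from_model(truth, 300, 0.25, seed=12)
        res = MultivariateLongitudinalModel(t, truth.spec).fit()
        a = 10.0
        df = t.data.copy()
        df["hct"] = df["hct"] * a
        t2 = CohortTable(df)
        model2 = MultivariateLongitudinalModel(t2, truth.spec)
        # transform fitted parameters: hct row/col of D and its residual
        # variance scale by a^2, hct coefficients by a
        D2 = res.D.to_numpy().copy()
        j = list(truth.spec.response_markers).index("hct")
        D2[j, :] *= a
        D2[:, j] *= a
        om2 = res.omega_variances.to_numpy().copy()
        om2[j] *= a**2
        beta2 = res.beta.to_numpy().copy()
        cols = [jj for jj, nm in enumerate(res.beta.index) if nm.startswith("hct:")]
        beta2[cols] *= a
        ll2 = log_likelihood(beta2, D2, om2, model2.designs)
        n = 300
        assert ll2 == pytest.approx(res.loglik - n * 2 * np.log(a), abs=1e-6)
        # and the refit on rescaled data attains (at least) this likelihood
        res2 = model2.fit()
        assert res2.loglik >= ll2 - 1e-3

    def test_univariate_agrees_with_statsmodels_mixedlm(self):
        statsmodels_api = pytest.importorskip("statsmodels.regression.mixed_linear_model")
        spec = ModelSpec(response_markers=("fbs",))
        truth = example_truth(spec)
        t = generate_from_model(truth, 300, 0.2, seed=13)
        res = MultivariateLongitudinalModel(t, spec).fit()
        d = build_design(t, spec)
        endog = d.Y.reshape(-1)
        exog = d.X.reshape(-1, d.k)
        groups = np.repeat(np.arange(d.n), 2)
        mlm = statsmodels_api.MixedLM(endog, exog, groups=groups)
        sm_res = mlm.fit(reml=False)
        assert res.loglik == pytest.approx(sm_res.llf, abs=1e-4)
        np.testing.assert_allclose(
            res.beta.to_numpy(), sm_res.fe_params, rtol=1e-4, atol=1e-5
        )

    def test_full_model_recovery_smoke(self):
        truth = example_truth()
        t = generate_from_model(truth, 2000, 0.2, seed=14)
        res = MultivariateLongitudinalModel(t, truth.spec).fit()
        assert res.converged
        se = res.bse.to_numpy()
        assert np.all(np.abs(res.beta.to_numpy() - truth.beta) < 4 * se)
        # covariance parameters in the right neighbourhood
        np.testing.assert_allclose(
            np.diag(res.D.to_numpy()), np.diag(truth.D), rtol=0.35
        )
        np.testing.assert_allclose(
            res.omega_variances.to_numpy(), truth.omega_variances, rtol=0.35
        )

    def test_serialization_round_trip(self, small_cohort):
        from gdmlda.mlmm import MLMMResults

        res = MultivariateLongitudinalModel(small_cohort).fit()
        back = MLMMResults.from_dict(res.to_dict())
        np.testing.assert_allclose(back.beta.to_numpy(), res.beta.to_numpy())
        np.testing.assert_allclose(back.D.to_numpy(), res.D.to_numpy())
        assert back.loglik == res.loglik

    def test_summary_renders(self, small_cohort):
        res = MultivariateLongitudinalModel(small_cohort).fit()
        text = res.summary()
        assert "log-likelihood" in text
        assert "fbs:group" in text
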
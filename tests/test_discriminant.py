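"""Allocation rule: worked scores, Bayes equivalence, priors, CV."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gdmlda.cohort import GDM, NON_GDM, CohortTable
from gdmlda.discriminant import (
    LongitudinalDiscriminant,
    StratificationError,
    allocate,
    allocation_threshold,
    cross_validate,
    discriminant_score,
    posterior,
)
from gdmlda.evaluation import auc_mann_whitney
from gdmlda.mlmm import ModelSpec, MultivariateLongitudinalModel, build_design
from gdmlda.simulate import default_generator_params, generate_cohort

from conftest import make_null_params


def _random_instance(rng, q):
    A = rng.standard_normal((q, q))
    V = A @ A.T + q * np.eye(q)
    mu1 = rng.standard_normal(q)
    mu2 = rng.standard_normal(q)
    y = rng.standard_normal(q) * 2
    pi2 = rng.uniform(0.05, 0.95)
    return y, mu1, mu2, V, 1 - pi2, pi2


class TestScore:
    def test_score_at_mu1_is_half_mahalanobis(self):
        rng = np.random.default_rng(0)
        y, mu1, mu2, V, *_ = _random_instance(rng, 4)
        L = discriminant_score(mu1, mu1, mu2, V)
        maha = (mu1 - mu2) @ np.linalg.solve(V, mu1 - mu2)
        assert L == pytest.approx(0.5 * maha)
        assert L > 0

    def test_score_at_midpoint_is_zero(self):
        rng = np.random.default_rng(1)
        y, mu1, mu2, V, *_ = _random_instance(rng, 3)
        mid = 0.5 * (mu1 + mu2)
        assert discriminant_score(mid, mu1, mu2, V) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_q2_example(self):
        L = discriminant_score(
            np.array([2.0, 2.0]),
            np.zeros(2),
            np.array([1.0, 1.0]),
            np.eye(2),
        )
        assert L == pytest.approx(-3.0)


class TestAllocate:
    def test_tie_goes_to_population_one(self):
        assert allocate(0.0, 0.5, 0.5) == NON_GDM

    def test_continues_worked_example(self):
        assert allocate(-3.0, 0.5, 0.5) == GDM

    def test_prior_proportion_threshold(self):
        # ln(0.082/0.918) ~ -2.415, so L = -2 still allocates non-GDM
        assert allocation_threshold(0.918, 0.082) == pytest.approx(
            np.log(0.082 / 0.918)
        )
        assert allocate(-2.0, 0.918, 0.082) == NON_GDM

    def test_prior_monotonicity(self):
        scores = np.linspace(-3, 3, 31)
        prev = None
        for pi2 in np.linspace(0.05, 0.95, 19):
            labels = allocate(scores, 1 - pi2, pi2)
            if prev is not None:
                # growing pi2 only ever converts non-GDM -> GDM
                assert np.all((prev == GDM) <= (labels == GDM))
            prev = labels

    def test_invalid_priors(self):
        with pytest.raises(ValueError):
            allocate(0.0, 0.9, 0.2)
        with pytest.raises(ValueError):
            allocate(0.0, 1.0, 0.0)


class TestPosterior:
    def test_midpoint_equal_priors(self):
        rng = np.random.default_rng(2)
        _, mu1, mu2, V, *_ = _random_instance(rng, 4)
        p1, p2 = posterior(0.5 * (mu1 + mu2), mu1, mu2, V, 0.5, 0.5)
        assert p1 == pytest.approx(0.5)
        assert p2 == pytest.approx(0.5)

    def test_identity_with_score(self):
        """log(p1/p2) = L + log(pi1/pi2) on 100 random instances."""
        rng = np.random.default_rng(3)
        for _ in range(100):
            q = int(rng.integers(1, 9))
            y, mu1, mu2, V, pi1, pi2 = _random_instance(rng, q)
            L = discriminant_score(y, mu1, mu2, V)
            p1, p2 = posterior(y, mu1, mu2, V, pi1, pi2)
            if min(p1, p2) > 1e-12:
                assert np.log(p1 / p2) == pytest.approx(
                    L + np.log(pi1 / pi2), abs=1e-10
                )

    def test_extreme_scores_no_nan(self):
        p1, p2 = posterior(
            np.array([700.0]), np.array([0.0]), np.array([1.0]), np.eye(1) * 1.0,
            0.5, 0.5,
        )
        assert np.isfinite(p1) and np.isfinite(p2)
        assert p1 + p2 == pytest.approx(1.0)

    def test_vanishing_prior_dominates(self):
        rng = np.random.default_rng(4)
        y, mu1, mu2, V, *_ = _random_instance(rng, 2)
        _, p2 = posterior(y, mu1, mu2, V, 1 - 1e-12, 1e-12)
        assert p2 < 1e-6


class TestBayesOracleEquivalence:
    def test_matches_direct_gaussian_bayes(self):
        """allocate(score) == argmax_g log pi_g + log N(y; mu_g, V)."""
        rng = np.random.default_rng(5)
        for _ in range(250):
            q = int(rng.choice([1, 2, 4, 8]))
            y, mu1, mu2, V, pi1, pi2 = _random_instance(rng, q)
            got = allocate(discriminant_score(y, mu1, mu2, V), pi1, pi2)
            lp1 = np.log(pi1) + stats.multivariate_normal.logpdf(y, mu1, V)
            lp2 = np.log(pi2) + stats.multivariate_normal.logpdf(y, mu2, V)
            want = NON_GDM if lp1 >= lp2 else GDM
            assert got == want


class TestInvariances:
    def test_affine_invariance(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            q = int(rng.choice([2, 4]))
            y, mu1, mu2, V, *_ = _random_instance(rng, q)
            L = discriminant_score(y, mu1, mu2, V)
            A = rng.standard_normal((q, q)) + 2 * np.eye(q)
            b = rng.standard_normal(q)
            L2 = discriminant_score(
                A @ y + b, A @ mu1 + b, A @ mu2 + b, A @ V @ A.T
            )
            assert L2 == pytest.approx(L, abs=1e-8 * max(1, abs(L)))

    def test_population_swap_flips_score_and_posteriors(self):
        rng = np.random.default_rng(7)
        y, mu1, mu2, V, pi1, pi2 = _random_instance(rng, 4)
        L = discriminant_score(y, mu1, mu2, V)
        L_swap = discriminant_score(y, mu2, mu1, V)
        assert L_swap == pytest.approx(-L)
        p1, p2 = posterior(y, mu1, mu2, V, pi1, pi2)
        q1, q2 = posterior(y, mu2, mu1, V, pi2, pi1)
        assert (p1, p2) == (pytest.approx(q2), pytest.approx(q1))


@pytest.fixture(scope="module")
def fitted(study_cohort):
    res = MultivariateLongitudinalModel(study_cohort).fit()
    return res, study_cohort


class TestClassifier:
    def test_group_means_ignore_observed_y(self, fitted):
        res, cohort = fitted
        clf = res.to_classifier()
        d = build_design(cohort, res.spec)
        mu1, mu2 = clf.conditional_group_means(d)
        d_perturbed = build_design(cohort, res.spec)
        d_perturbed.Y = d.Y + 100.0
        mu1b, mu2b = clf.conditional_group_means(d_perturbed)
        np.testing.assert_array_equal(mu1, mu1b)
        np.testing.assert_array_equal(mu2, mu2b)

    def test_group_effect_difference_replicates_over_visits(self, fitted):
        res, cohort = fitted
        clf = res.to_classifier()
        d = build_design(cohort, res.spec)
        mu1, mu2 = clf.conditional_group_means(d)
        diff = mu2 - mu1
        gcoefs = np.array(
            [res.beta[f"{m}:group"] for m in res.spec.response_markers]
        )
        np.testing.assert_allclose(diff[0], np.repeat(gcoefs, 2), atol=1e-10)
        assert np.allclose(diff, diff[0])  # same for every subject

    def test_classification_deterministic(self, fitted):
        res, cohort = fitted
        a = res.to_classifier().classify(cohort).table
        b = res.to_classifier().classify(cohort).table
        pd.testing.assert_frame_equal(a, b)

    def test_posterior_label_consistency(self, fitted):
        res, cohort = fitted
        cr = res.to_classifier().classify(cohort)
        t = cr.table
        assert np.allclose(t["posterior1"] + t["posterior2"], 1.0)
        # label agrees with score vs threshold
        thr = cr.threshold
        np.testing.assert_array_equal(
            t["label"].to_numpy(), np.where(t["score"] >= thr, 1, 2)
        )

    def test_null_cohort_prior_dominates(self, default_params):
        params = make_null_params(replace(default_params, n_subjects=400))
        t = generate_cohort(params, seed=31)
        res = MultivariateLongitudinalModel(t).fit()
        cr = res.to_classifier().classify(t)
        # uninformative score + pi1 >> pi2: almost everyone allocated non-GDM
        assert np.mean(cr.labels == NON_GDM) > 0.9


class TestCrossValidation:
    def test_leave_one_out_mechanics(self, default_params):
        params = replace(default_params, n_subjects=40, prevalence=0.25)
        t = generate_cohort(params, seed=41)
        spec = ModelSpec(response_markers=("fbs",))
        cr = cross_validate(t, spec, folds=40, seed=0)
        assert len(cr.table) == 40
        assert cr.provenance == "cross-validated"

    def test_same_seed_same_folds(self, default_params):
        params = replace(default_params, n_subjects=80, prevalence=0.2)
        t = generate_cohort(params, seed=42)
        spec = ModelSpec(response_markers=("fbs",))
        a = cross_validate(t, spec, folds=4, seed=3).table
        b = cross_validate(t, spec, folds=4, seed=3).table
        pd.testing.assert_frame_equal(a, b)

    def test_training_split_missing_group_raises(self, default_params):
        params = replace(default_params, n_subjects=30, prevalence=0.0)
        t = generate_cohort(params, seed=43)
        df = t.data.copy()
        df.loc[df["subject_id"] == 1, "group"] = GDM  # exactly one GDM subject
        with pytest.raises(StratificationError):
            with pytest.warns(UserWarning):
                cross_validate(CohortTable(df), folds=2, seed=0)

    def test_cv_auc_close_to_resubstitution_under_strong_signal(
        self, study_cohort
    ):
        res = MultivariateLongitudinalModel(study_cohort).fit()
        cr_resub = res.to_classifier().classify(study_cohort)
        cr_cv = cross_validate(study_cohort, folds=10, seed=1)
        auc_resub = auc_mann_whitney(cr_resub.scores, cr_resub.true_groups)
        auc_cv = auc_mann_whitney(cr_cv.scores, cr_cv.true_groups)
        assert abs(auc_cv - auc_resub) < 0.05
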
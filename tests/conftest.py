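"""Shared fixtures: calibrated generator params, small cohorts, model truths."""

from dataclasses import replace

import numpy as np
import pytest

from gdmlda.mlmm import ModelSpec
from gdmlda.simulate import (
    GeneratorParams,
    ModelTruth,
    default_generator_params,
    generate_cohort,
)


@pytest.fixture(scope="session")
def default_params() -> GeneratorParams:
    return default_generator_params()


@pytest.fixture(scope="session")
def small_cohort(default_params):
    """A 200-subject calibrated cohort, reused across read-only tests."""
    params = replace(default_params, n_subjects=200)
    return generate_cohort(params, seed=1234)


@pytest.fixture(scope="session")
def study_cohort(default_params):
    """Full-size (n=600) calibrated cohort."""
    return generate_cohort(default_params, seed=99)


def make_null_params(base: GeneratorParams) -> GeneratorParams:
    """Zero group effect: GDM means/SDs copied from non-GDM."""
    means = dict(base.marker_means)
    sds = dict(base.marker_sds)
    for (m, g, v) in list(means):
        if g == 2:
            means[(m, g, v)] = means[(m, 1, v)]
            sds[(m, g, v)] = sds[(m, 1, v)]
    return replace(base, marker_means=means, marker_sds=sds)


def example_truth(spec: ModelSpec | None = None) -> ModelTruth:
    """A plausible ground truth for model-exact simulation.

    Intercepts/group/time effects echo the calibrated cohort's biomarker
    levels; covariate coefficients are small but nonzero; D has positive
    cross-marker covariances and the residual variances split each
    marker's dispersion roughly in half.
    """
    if spec is None:
        spec = ModelSpec()
    per_marker = {
        # marker: (intercept, group, time, age, bmi, sbp, dbp)
        "hb": (12.0, 0.6, -0.7, 0.01, 0.01, 0.002, -0.002),
        "hct": (36.0, 1.9, -1.7, 0.02, 0.03, 0.005, -0.005),
        "fbs": (80.0, 12.0, -2.0, 0.05, 0.10, 0.010, -0.010),
        "rbc": (4.1, 0.2, -0.3, 0.002, 0.002, 0.0005, -0.0005),
    }
    beta = []
    for m in spec.response_markers:
        coefs = per_marker[m]
        beta.extend(coefs[: len(spec.terms)])
    sigma2 = {"hb": 0.9, "hct": 9.0, "fbs": 130.0, "rbc": 0.2}
    p = spec.n_markers
    d_diag = np.array([0.5 * sigma2[m] for m in spec.response_markers])
    corr = 0.3 * np.ones((p, p)) + 0.7 * np.eye(p)
    D = corr * np.sqrt(np.outer(d_diag, d_diag))
    omega = np.array([0.5 * sigma2[m] for m in spec.response_markers])
    return ModelTruth(beta=np.array(beta), D=D, omega_variances=omega, spec=spec)
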
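"""Seeded synthetic-cohort generators.

The real screening cohort this package's defaults emulate (a prospective
sample of 600 pregnant women, 8.2% of whom developed GDM, with the four CBC
biomarkers measured in the first and early second trimesters) is not
publicly deposited, so every downstream stage is exercised on synthetic
data.  Two generators are provided:

``generate_cohort``
    *Label-first, moment-calibrated*: the GDM label is drawn Bernoulli
    (prevalence) and the 8-vector of biomarkers (4 markers x 2 visits) is
    drawn from a group-conditional multivariate normal whose means/SDs are
    the calibration targets.  The published cohort summaries supply means
    and SDs only, so the correlation structure is an explicit, documented
    assumption (see :func:`default_generator_params`).

``generate_from_model``
    *Model-exact*: responses are built as ``y_i = X_i beta + Z_i b_i +
    eps_i`` with ``b_i ~ N(0, D)`` and ``eps_i ~ N(0, Omega)`` -- the exact
    data-generating process of the longitudinal mixed model, used for
    parameter-recovery studies.

Both are bit-deterministic given (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .cohort import (
    BIOMARKERS,
    CATEGORICALS,
    COLUMNS,
    COVARIATES,
    GDM,
    NON_GDM,
    VISITS,
    CohortTable,
)

if TYPE_CHECKING:  # pragma: no cover
    from .mlmm import ModelSpec

_GROUPS = (NON_GDM, GDM)


class GeneratorParamError(ValueError):
    """Generator parameters violate an invariant (e.g. non-PD covariance)."""


@dataclass(frozen=True)
class CovariateParams:
    """Covariate distributions per group (and per visit where time-varying).

    Continuous covariates are normal with the given (mean, sd); parity is
    categorical on {0,1,2,3}; education is Bernoulli on 'academic'.
    Keys: ``age[group]``; ``bmi/sbp/dbp[(group, visit)]``;
    ``parity_probs[group]``; ``p_academic[group]``.
    """

    age: dict
    bmi: dict
    sbp: dict
    dbp: dict
    parity_probs: dict
    p_academic: dict


@dataclass(frozen=True)
class GeneratorParams:
    """Calibration targets and correlation assumptions for the generator.

    ``marker_means`` / ``marker_sds`` are keyed by ``(marker, group,
    visit)`` with marker in :data:`~gdmlda.cohort.BIOMARKERS`, group in
    {1, 2} and visit in {1, 2}.  The implied 8x8 group covariance is
    ``diag(sd) (R (x) T) diag(sd)`` in visits-within-marker stacking order,
    where ``R`` is the 4x4 cross-marker correlation, ``T`` the 2x2
    within-marker across-visit correlation ``[[1, rho], [rho, 1]]``, and
    ``(x)`` the Kronecker product; it is positive definite iff ``R`` is and
    ``|rho| < 1``.
    """

    n_subjects: int
    prevalence: float
    marker_means: dict
    marker_sds: dict
    cross_marker_corr: np.ndarray
    within_marker_corr: float
    covariates: CovariateParams
    seed: int | None = None

    def __post_init__(self):
        object.__setattr__(
            self, "cross_marker_corr", np.asarray(self.cross_marker_corr, float)
        )
        self.validate()

    def validate(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise GeneratorParamError("prevalence must be in [0, 1]")
        if self.n_subjects < 1:
            raise GeneratorParamError("n_subjects must be >= 1")
        R = self.cross_marker_corr
        p = len(BIOMARKERS)
        if R.shape != (p, p):
            raise GeneratorParamError(f"cross_marker_corr must be {p}x{p}")
        if not np.allclose(R, R.T):
            raise GeneratorParamError("cross_marker_corr must be symmetric")
        if not np.allclose(np.diag(R), 1.0):
            raise GeneratorParamError("cross_marker_corr must have unit diagonal")
        if not abs(self.within_marker_corr) < 1.0:
            raise GeneratorParamError("|within_marker_corr| must be < 1")
        for key, sd in self.marker_sds.items():
            if not sd > 0:
                raise GeneratorParamError(f"SD for {key} must be > 0")
        for g in _GROUPS:
            cov = self.group_covariance(g)
            if np.linalg.eigvalsh(cov).min() <= 0:
                raise GeneratorParamError(
                    f"implied 8x8 covariance for group {g} is not positive "
                    "definite"
                )

    # -- implied moments (visits-within-marker stacking order) -----------

    def group_mean_vector(self, group: int) -> np.ndarray:
        return np.array(
            [self.marker_means[(m, group, v)] for m in BIOMARKERS for v in VISITS]
        )

    def group_sd_vector(self, group: int) -> np.ndarray:
        return np.array(
            [self.marker_sds[(m, group, v)] for m in BIOMARKERS for v in VISITS]
        )

    def correlation_matrix(self) -> np.ndarray:
        rho = self.within_marker_corr
        T = np.array([[1.0, rho], [rho, 1.0]])
        return np.kron(self.cross_marker_corr, T)

    def group_covariance(self, group: int) -> np.ndarray:
        sd = self.group_sd_vector(group)
        return self.correlation_matrix() * np.outer(sd, sd)

    # -- (de)serialization ------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "prevalence": self.prevalence,
            "marker_means": {
                f"{m}/{g}/{v}": float(x) for (m, g, v), x in self.marker_means.items()
            },
            "marker_sds": {
                f"{m}/{g}/{v}": float(x) for (m, g, v), x in self.marker_sds.items()
            },
            "cross_marker_corr": self.cross_marker_corr.tolist(),
            "within_marker_corr": self.within_marker_corr,
            "covariates": {
                "age": {str(k): list(v) for k, v in self.covariates.age.items()},
                "bmi": {f"{g}/{v}": list(x) for (g, v), x in self.covariates.bmi.items()},
                "sbp": {f"{g}/{v}": list(x) for (g, v), x in self.covariates.sbp.items()},
                "dbp": {f"{g}/{v}": list(x) for (g, v), x in self.covariates.dbp.items()},
                "parity_probs": {
                    str(k): list(v) for k, v in self.covariates.parity_probs.items()
                },
                "p_academic": {
                    str(k): float(v) for k, v in self.covariates.p_academic.items()
                },
            },
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorParams":
        def _unkey3(dd):
            out = {}
            for k, v in dd.items():
                m, g, vis = k.split("/")
                out[(m, int(g), int(vis))] = float(v)
            return out

        def _unkey2(dd):
            out = {}
            for k, v in dd.items():
                g, vis = k.split("/")
                out[(int(g), int(vis))] = tuple(v)
            return out

        cov = d["covariates"]
        covariates = CovariateParams(
            age={int(k): tuple(v) for k, v in cov["age"].items()},
            bmi=_unkey2(cov["bmi"]),
            sbp=_unkey2(cov["sbp"]),
            dbp=_unkey2(cov["dbp"]),
            parity_probs={int(k): tuple(v) for k, v in cov["parity_probs"].items()},
            p_academic={int(k): float(v) for k, v in cov["p_academic"].items()},
        )
        return cls(
            n_subjects=int(d["n_subjects"]),
            prevalence=float(d["prevalence"]),
            marker_means=_unkey3(d["marker_means"]),
            marker_sds=_unkey3(d["marker_sds"]),
            cross_marker_corr=np.asarray(d["cross_marker_corr"], float),
            within_marker_corr=float(d["within_marker_corr"]),
            covariates=covariates,
            seed=d.get("seed"),
        )


def default_covariate_params() -> CovariateParams:
    """Covariate distributions calibrated to the reference cohort summaries."""
    return CovariateParams(
        age={NON_GDM: (27.19, 3.93), GDM: (28.35, 3.89)},
        bmi={
            (NON_GDM, 1): (24.89, 4.30),
            (NON_GDM, 2): (29.73, 4.11),
            (GDM, 1): (26.09, 5.02),
            (GDM, 2): (30.90, 4.45),
        },
        sbp={
            (NON_GDM, 1): (101.79, 12.31),
            (NON_GDM, 2): (106.56, 14.43),
            (GDM, 1): (101.73, 10.78),
            (GDM, 2): (112.55, 13.62),
        },
        dbp={
            (NON_GDM, 1): (64.20, 7.70),
            (NON_GDM, 2): (66.16, 9.57),
            (GDM, 1): (63.47, 8.05),
            (GDM, 2): (70.01, 10.60),
        },
        # category shares among non-GDM (n=551) and GDM (n=49) women
        parity_probs={
            NON_GDM: (1 / 551, 260 / 551, 224 / 551, 66 / 551),
            GDM: (0.0, 28 / 49, 15 / 49, 6 / 49),
        },
        p_academic={NON_GDM: 152 / 551, GDM: 11 / 49},
    )


def default_generator_params() -> GeneratorParams:
    """Generator defaults calibrated to the reference screening cohort.

    Means and SDs per (marker, group, visit) are the published group x
    trimester summaries of that cohort (n=600, GDM prevalence 8.2%).  The
    summaries print no correlations, so the correlation defaults are
    physiologically plausible *assumptions*, not cohort-derived: 0.65
    between Hb and Hct, 0.45 between RBC and each of Hb/Hct, 0.10 between
    FBS and the hematologic markers, and 0.5 between the two visits of the
    same marker.

    The non-GDM visit-1 RBC SD is set to 0.51: the value of 5.01 printed in
    the source summary is physiologically impossible for a mean of 4.39
    x10^12/L and is treated as a typographical error.
    """
    means = {
        # (marker, group, visit): mean
        ("rbc", GDM, 1): 4.58, ("rbc", GDM, 2): 4.19,
        ("rbc", NON_GDM, 1): 4.39, ("rbc", NON_GDM, 2): 4.12,
        ("hb", GDM, 1): 13.22, ("hb", GDM, 2): 12.32,
        ("hb", NON_GDM, 1): 12.63, ("hb", NON_GDM, 2): 11.89,
        ("hct", GDM, 1): 39.53, ("hct", GDM, 2): 36.87,
        ("hct", NON_GDM, 1): 37.55, ("hct", NON_GDM, 2): 35.86,
        ("fbs", GDM, 1): 92.04, ("fbs", GDM, 2): 96.96,
        ("fbs", NON_GDM, 1): 83.19, ("fbs", NON_GDM, 2): 81.08,
    }
    sds = {
        ("rbc", GDM, 1): 0.45, ("rbc", GDM, 2): 0.41,
        ("rbc", NON_GDM, 1): 0.51,  # corrected; source prints 5.01 (typo)
        ("rbc", NON_GDM, 2): 0.45,
        ("hb", GDM, 1): 1.17, ("hb", GDM, 2): 0.90,
        ("hb", NON_GDM, 1): 0.99, ("hb", NON_GDM, 2): 0.97,
        ("hct", GDM, 1): 3.35, ("hct", GDM, 2): 2.54,
        ("hct", NON_GDM, 1): 3.54, ("hct", NON_GDM, 2): 2.88,
        ("fbs", GDM, 1): 12.01, ("fbs", GDM, 2): 12.74,
        ("fbs", NON_GDM, 1): 11.75, ("fbs", NON_GDM, 2): 10.17,
    }
    # BIOMARKERS order: hb, hct, fbs, rbc
    R = np.array(
        [
            [1.00, 0.65, 0.10, 0.45],
            [0.65, 1.00, 0.10, 0.45],
            [0.10, 0.10, 1.00, 0.10],
            [0.45, 0.45, 0.10, 1.00],
        ]
    )
    return GeneratorParams(
        n_subjects=600,
        prevalence=0.082,
        marker_means=means,
        marker_sds=sds,
        cross_marker_corr=R,
        within_marker_corr=0.5,
        covariates=default_covariate_params(),
    )


def _draw_covariates(
    rng: np.random.Generator, groups: np.ndarray, cov: CovariateParams
) -> dict[str, np.ndarray]:
    """Draw covariates for all subjects; returns per-visit arrays.

    Draw order is fixed (age, bmi, sbp, dbp, parity, education) so output
    is reproducible for a given generator state.
    """
    n = groups.size
    out: dict[str, np.ndarray] = {}
    z_age = rng.standard_normal(n)
    age = np.empty(n)
    for g in _GROUPS:
        m, s = cov.age[g]
        age[groups == g] = m + s * z_age[groups == g]
    out["age"] = age
    for name, params in (("bmi", cov.bmi), ("sbp", cov.sbp), ("dbp", cov.dbp)):
        z = rng.standard_normal((n, 2))
        vals = np.empty((n, 2))
        for g in _GROUPS:
            mask = groups == g
            for j, v in enumerate(VISITS):
                m, s = params[(g, v)]
                vals[mask, j] = m + s * z[mask, j]
        out[name] = vals
    u = rng.random(n)
    parity = np.empty(n, dtype=int)
    for g in _GROUPS:
        cum = np.cumsum(cov.parity_probs[g])
        cum[-1] = 1.0
        parity[groups == g] = np.searchsorted(cum, u[groups == g], side="right")
    out["parity"] = parity
    u = rng.random(n)
    academic = np.empty(n, dtype=bool)
    for g in _GROUPS:
        academic[groups == g] = u[groups == g] < cov.p_academic[g]
    out["education"] = np.where(academic, "academic", "non-academic")
    return out


def _assemble_long(
    groups: np.ndarray,
    markers: np.ndarray,
    covs: dict[str, np.ndarray],
    subject_ids: np.ndarray | None = None,
) -> CohortTable:
    """Build the long-format table from per-subject arrays.

    ``markers`` has shape (n, 8) in visits-within-marker order.
    """
    n = groups.size
    if subject_ids is None:
        subject_ids = np.arange(1, n + 1)
    rows = {
        "subject_id": np.repeat(subject_ids, 2),
        "visit": np.tile([1, 2], n),
        "group": np.repeat(groups, 2),
    }
    for j, m in enumerate(BIOMARKERS):
        # marker m occupies columns 2j (visit 1) and 2j+1 (visit 2)
        rows[m] = markers[:, 2 * j : 2 * j + 2].reshape(-1)
    rows["age"] = np.repeat(covs["age"], 2)
    for name in ("bmi", "sbp", "dbp"):
        rows[name] = covs[name].reshape(-1)
    rows["parity"] = np.repeat(covs["parity"], 2)
    rows["education"] = np.repeat(covs["education"], 2)
    df = pd.DataFrame(rows, columns=list(COLUMNS))
    return CohortTable.from_dataframe(df, validate=False)


def generate_cohort(params: GeneratorParams, seed: int | None = None) -> CohortTable:
    """Draw a moment-calibrated synthetic cohort (label-first generation).

    Group labels are Bernoulli(prevalence); biomarkers are group-conditional
    multivariate normal with the configured means/SDs and correlation
    structure; covariates follow ``params.covariates``.  Deterministic given
    (params, seed).
    """
    if seed is None:
        seed = params.seed
    if seed is None:
        raise GeneratorParamError("a seed is required (argument or params.seed)")
    params.validate()
    rng = np.random.default_rng(seed)
    n = params.n_subjects
    groups = np.where(rng.random(n) < params.prevalence, GDM, NON_GDM)
    z = rng.standard_normal((n, 8))
    markers = np.empty((n, 8))
    for g in _GROUPS:
        mask = groups == g
        if not mask.any():
            continue
        L = np.linalg.cholesky(params.group_covariance(g))
        markers[mask] = params.group_mean_vector(g) + z[mask] @ L.T
    covs = _draw_covariates(rng, groups, params.covariates)
    return _assemble_long(groups, markers, covs)


# --------------------------------------------------------------------------
# model-exact generation


@dataclass(frozen=True)
class ModelTruth:
    """Ground-truth parameters for model-exact simulation.

    ``beta`` is ordered as the design columns of ``spec`` (see
    :class:`gdmlda.mlmm.ModelSpec`); ``D`` is the p x p random-intercept
    covariance; ``omega_variances`` the per-marker residual variances.
    """

    beta: np.ndarray
    D: np.ndarray
    omega_variances: np.ndarray
    spec: "ModelSpec"

    def __post_init__(self):
        object.__setattr__(self, "beta", np.asarray(self.beta, float))
        object.__setattr__(self, "D", np.asarray(self.D, float))
        object.__setattr__(
            self, "omega_variances", np.asarray(self.omega_variances, float)
        )
        p = self.spec.n_markers
        if self.D.shape != (p, p) or not np.allclose(self.D, self.D.T):
            raise GeneratorParamError(f"D must be symmetric {p}x{p}")
        if np.linalg.eigvalsh(self.D).min() < -1e-10:
            raise GeneratorParamError("D must be positive semi-definite")
        if self.omega_variances.shape != (p,) or (self.omega_variances <= 0).any():
            raise GeneratorParamError("omega_variances must be p positive values")
        if self.beta.shape != (self.spec.k,):
            raise GeneratorParamError(
                f"beta has length {self.beta.size}, design expects {self.spec.k}"
            )


def generate_from_model(
    truth: ModelTruth,
    n_subjects: int,
    prevalence: float,
    seed: int,
    covariates: CovariateParams | None = None,
) -> CohortTable:
    """Simulate exactly from ``y_i = X_i beta + Z_i b_i + eps_i``.

    Covariates and group labels are drawn as in :func:`generate_cohort`;
    responses are the mixed-model mean plus random intercepts ``b_i ~
    N(0, D)`` (one per marker) and residuals ``eps_i ~ N(0, Omega)`` with
    diagonal ``Omega = diag(omega_variances) (x) I_2``.
    """
    from .mlmm import build_design

    if covariates is None:
        covariates = default_covariate_params()
    rng = np.random.default_rng(seed)
    n = n_subjects
    groups = np.where(rng.random(n) < prevalence, GDM, NON_GDM)
    covs = _draw_covariates(rng, groups, covariates)
    p = truth.spec.n_markers
    # skeleton with placeholder responses; X depends only on covariates
    placeholder = np.ones((n, 8))
    skeleton = _assemble_long(groups, placeholder, covs)
    designs = build_design(skeleton, truth.spec)
    mean = designs.X @ truth.beta  # (n, q)
    # PSD-safe square root of D (cholesky fails at D = 0)
    evals, evecs = np.linalg.eigh(truth.D)
    D_sqrt = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None))) @ evecs.T
    b = rng.standard_normal((n, p)) @ D_sqrt.T
    eps_sd = np.repeat(np.sqrt(truth.omega_variances[: p]), 2)
    eps = rng.standard_normal((n, designs.q)) * eps_sd
    Y = mean + b @ designs.Z.T + eps
    # write responses back into the long frame (only modelled markers)
    full = np.ones((n, 8))
    for jm, m in enumerate(BIOMARKERS):
        if m in truth.spec.response_markers:
            jr = truth.spec.response_markers.index(m)
            full[:, 2 * jm : 2 * jm + 2] = Y[:, 2 * jr : 2 * jr + 2]
    return _assemble_long(groups, full, covs)


# --------------------------------------------------------------------------
# optional consistency layer: synthetic glucose screening panels


def synthesize_screening_panels(
    groups: np.ndarray, seed: int, subject_ids: np.ndarray | None = None
) -> pd.DataFrame:
    """Draw GLT/OGTT glucose values consistent with given group labels.

    A convenience layer for exercising the two-step diagnosis rule: GDM
    subjects receive a triggering GLT (>= 140 mg/dL) and an OGTT meeting at
    least two Carpenter & Coustan criteria; non-GDM subjects receive either
    a sub-threshold GLT or a negative OGTT.  Values are drawn from plausible
    plasma-glucose ranges; this is synthetic plumbing, not a physiologic
    glucose model.
    """
    from .screening import CC_THRESHOLDS, GLT_THRESHOLD

    rng = np.random.default_rng(seed)
    groups = np.asarray(groups)
    n = groups.size
    if subject_ids is None:
        subject_ids = np.arange(1, n + 1)
    glt = np.where(
        groups == GDM,
        GLT_THRESHOLD + rng.uniform(0, 40, n),
        rng.uniform(90, 160, n),
    )
    panel = np.column_stack(
        [rng.uniform(0.75, 0.98, n) * t for t in CC_THRESHOLDS]
    )
    is_gdm = groups == GDM
    # push two random criteria over threshold for GDM subjects
    for i in np.flatnonzero(is_gdm):
        met = rng.choice(4, size=2, replace=False)
        for j in met:
            panel[i, j] = CC_THRESHOLDS[j] * rng.uniform(1.0, 1.2)
    # non-GDM subjects with a triggering GLT keep a negative panel (at most
    # one criterion met); ensured by construction above
    out = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "glt_1h": glt,
            "fasting": panel[:, 0],
            "h1": panel[:, 1],
            "h2": panel[:, 2],
            "h3": panel[:, 3],
        }
    )
    out.loc[~is_gdm & (glt < GLT_THRESHOLD), ["fasting", "h1", "h2", "h3"]] = np.nan
    return out
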
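"""Multivariate longitudinal linear mixed model.

The model for subject *i* stacks p biomarkers at t=2 prenatal visits into a
response vector ``y_i`` of length q = 2p (visits nested within biomarker,
biomarkers in canonical order) and assumes

    y_i = X_i beta + Z_i b_i + eps_i,   b_i ~ N(0, D),  eps_i ~ N(0, Omega)

with one random intercept per biomarker (``Z_i = I_p (x) 1_2``, unstructured
p x p ``D``) and a diagonal residual covariance with biomarker-specific
variances (``Omega = diag(sigma^2_m) (x) I_2``).  Cross-biomarker and
cross-visit dependence is therefore carried entirely by ``D``; with only two
visits this is the richest random structure that is identifiable (random
slopes are not).

The mean structure is seemingly-unrelated-regressions style: every
covariate gets a biomarker-specific coefficient, since the responses live
on incommensurate scales (g/dL vs mg/dL).  Default covariates per
biomarker: intercept, GDM-group indicator (0 = non-GDM, 1 = GDM), visit
indicator (0/1), age, BMI, SBP, DBP; a group x time interaction is
available behind a flag and off by default.

Estimation is direct maximum likelihood: ``beta`` is profiled out by GLS
for each covariance parameter vector ``theta`` (log-Cholesky for ``D``,
log-variances for ``Omega``) and the profile likelihood is maximized by
L-BFGS-B.  Because the design is balanced (complete two-visit data), the
marginal covariance ``V = Z D Z' + Omega`` is common to all subjects and
the profile likelihood depends on the data only through second-moment
matrices accumulated once per dataset, so each likelihood evaluation costs
O(q^2 k^2) regardless of n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy import optimize, stats

from .cohort import BIOMARKERS, GDM, CohortTable

_LOG_2PI = np.log(2.0 * np.pi)


class RankDeficiencyError(ValueError):
    """The fixed-effects design is rank deficient; names collinear columns."""


class CovarianceError(ValueError):
    """A covariance matrix is not positive definite."""


@dataclass(frozen=True)
class ModelSpec:
    """Mean/covariance structure choices for the longitudinal model."""

    response_markers: tuple[str, ...] = BIOMARKERS
    fixed_covariates: tuple[str, ...] = ("age", "bmi", "sbp", "dbp")
    include_group_time_interaction: bool = False
    error_structure: str = "diagonal"

    def __post_init__(self):
        object.__setattr__(
            self, "response_markers", tuple(self.response_markers)
        )
        object.__setattr__(self, "fixed_covariates", tuple(self.fixed_covariates))
        if not self.response_markers:
            raise ValueError("response_markers must be non-empty")
        unknown = set(self.response_markers) - set(BIOMARKERS)
        if unknown:
            raise ValueError(f"unknown biomarker(s): {sorted(unknown)}")
        if self.error_structure != "diagonal":
            raise ValueError(
                "only the diagonal error structure is supported "
                f"(got {self.error_structure!r})"
            )

    @property
    def terms(self) -> tuple[str, ...]:
        base = ("const", "group", "time", *self.fixed_covariates)
        if self.include_group_time_interaction:
            base = (*base, "group:time")
        return base

    @property
    def n_markers(self) -> int:
        return len(self.response_markers)

    @property
    def q(self) -> int:
        return 2 * self.n_markers

    @property
    def k(self) -> int:
        return self.n_markers * len(self.terms)

    @property
    def coef_names(self) -> tuple[str, ...]:
        return tuple(
            f"{m}:{t}" for m in self.response_markers for t in self.terms
        )

    def to_dict(self) -> dict:
        return {
            "response_markers": list(self.response_markers),
            "fixed_covariates": list(self.fixed_covariates),
            "include_group_time_interaction": self.include_group_time_interaction,
            "error_structure": self.error_structure,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            response_markers=tuple(d["response_markers"]),
            fixed_covariates=tuple(d["fixed_covariates"]),
            include_group_time_interaction=bool(
                d.get("include_group_time_interaction", False)
            ),
            error_structure=d.get("error_structure", "diagonal"),
        )


@dataclass
class StackedDesign:
    """Per-subject view of the stacked design (visits within biomarker)."""

    subject_id: object
    group: int
    y: np.ndarray  # (q,)
    X: np.ndarray  # (q, k)
    Z: np.ndarray  # (q, p)


@dataclass
class StackedDesignSet:
    """All subjects' stacked designs as dense arrays.

    ``Y`` is (n, q), ``X`` is (n, q, k); ``Z`` is shared across subjects in
    a balanced design.
    """

    spec: ModelSpec
    subject_ids: np.ndarray
    groups: np.ndarray  # (n,) in {1, 2}
    Y: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    coef_names: tuple[str, ...]

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def q(self) -> int:
        return self.Y.shape[1]

    @property
    def k(self) -> int:
        return self.X.shape[2]

    def subject(self, i: int) -> StackedDesign:
        return StackedDesign(
            subject_id=self.subject_ids[i],
            group=int(self.groups[i]),
            y=self.Y[i],
            X=self.X[i],
            Z=self.Z,
        )

    def __iter__(self) -> Iterator[StackedDesign]:
        return (self.subject(i) for i in range(self.n))

    def __len__(self) -> int:
        return self.n

    def group_column_indices(self) -> np.ndarray:
        """Indices of the per-biomarker group-indicator columns in X."""
        return np.array(
            [j for j, name in enumerate(self.coef_names) if name.endswith(":group")]
        )

    def subset(self, mask: np.ndarray) -> "StackedDesignSet":
        return StackedDesignSet(
            spec=self.spec,
            subject_ids=self.subject_ids[mask],
            groups=self.groups[mask],
            Y=self.Y[mask],
            X=self.X[mask],
            Z=self.Z,
            coef_names=self.coef_names,
        )


def random_effects_design(p: int) -> np.ndarray:
    """Z for random intercepts: block-diagonal ones per biomarker, (2p, p)."""
    return np.kron(np.eye(p), np.ones((2, 1)))


def build_design(table: CohortTable, spec: ModelSpec | None = None) -> StackedDesignSet:
    """Assemble stacked responses and design matrices from a cohort.

    Row order within a subject is canonical (visits nested within biomarker
    in spec order) regardless of input row order.  The group indicator is
    coded 0 = non-GDM, 1 = GDM inside X; the {1, 2} labels are retained in
    ``groups``.
    """
    if spec is None:
        spec = ModelSpec()
    df = table.data.sort_values(["subject_id", "visit"], kind="mergesort")
    needed = set(spec.fixed_covariates) | set(spec.response_markers) | {"group"}
    missing = needed - set(df.columns)
    if missing:
        from .cohort import SchemaError

        raise SchemaError(f"missing design column(s): {sorted(missing)}")
    n_rows = len(df)
    if n_rows % 2:
        raise ValueError("cohort must have exactly two rows per subject")
    n = n_rows // 2
    subject_ids = df["subject_id"].to_numpy()[::2]
    groups = df["group"].to_numpy(int)[::2]
    gind = (groups == GDM).astype(float)  # 0/1 indicator

    p = spec.n_markers
    terms = spec.terms
    n_terms = len(terms)
    q, k = spec.q, spec.k

    cov_wide = {
        c: df[c].to_numpy(float).reshape(n, 2) for c in spec.fixed_covariates
    }
    Y = np.empty((n, q))
    X = np.zeros((n, q, k))
    for jm, m in enumerate(spec.response_markers):
        vals = df[m].to_numpy(float).reshape(n, 2)
        for jv in range(2):
            r = 2 * jm + jv
            Y[:, r] = vals[:, jv]
            base = jm * n_terms
            for s, t in enumerate(terms):
                col = base + s
                if t == "const":
                    X[:, r, col] = 1.0
                elif t == "group":
                    X[:, r, col] = gind
                elif t == "time":
                    X[:, r, col] = float(jv)
                elif t == "group:time":
                    X[:, r, col] = gind * jv
                else:
                    X[:, r, col] = cov_wide[t][:, jv]
    return StackedDesignSet(
        spec=spec,
        subject_ids=subject_ids,
        groups=groups,
        Y=Y,
        X=X,
        Z=random_effects_design(p),
        coef_names=spec.coef_names,
    )


# --------------------------------------------------------------------------
# covariance assembly and likelihood


def marginal_covariance(
    D: np.ndarray, omega_variances: np.ndarray, check: bool = True
) -> np.ndarray:
    """Marginal covariance V = Z D Z' + Omega of one subject's stack.

    ``Omega = diag(omega_variances) (x) I_2`` (diagonal structure).
    """
    D = np.asarray(D, float)
    omega_variances = np.asarray(omega_variances, float)
    p = D.shape[0]
    Z = random_effects_design(p)
    V = Z @ D @ Z.T + np.kron(np.diag(omega_variances), np.eye(2))
    if check:
        try:
            np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            raise CovarianceError(
                "marginal covariance is not positive definite; "
                f"D={D.tolist()}, omega={omega_variances.tolist()}"
            ) from None
    return V


class _SufficientStats:
    """Second-moment accumulator making the profile likelihood O(1) in n.

    With ``G_i = [X_i, y_i]`` (q x (k+1)), stores ``C[j, l] = sum_i
    g_ij g_il'`` (q x q blocks) so that for any weight matrix ``W``:
    ``sum_i X_i' W X_i``, ``sum_i X_i' W y_i`` and ``sum_i y_i' W y_i`` are
    tensor contractions of C with W.
    """

    def __init__(self, X: np.ndarray, Y: np.ndarray):
        n, q, k = X.shape
        G = np.concatenate([X, Y[:, :, None]], axis=2)  # (n, q, k+1)
        G2 = G.reshape(n, q * (k + 1))
        C_full = G2.T @ G2  # ((q(k+1)), (q(k+1)))
        C = C_full.reshape(q, k + 1, q, k + 1).transpose(1, 3, 0, 2)
        self.C = np.ascontiguousarray(C)  # (k+1, k+1, q, q)
        self.n, self.q, self.k = n, q, k

    def weighted_moments(self, W: np.ndarray):
        M = np.tensordot(self.C, W, axes=([2, 3], [0, 1]))
        A = M[: self.k, : self.k]
        c = M[: self.k, self.k]
        yy = M[self.k, self.k]
        return A, c, yy


def _check_rank(designs: StackedDesignSet) -> None:
    n, q, k = designs.X.shape
    Xs = designs.X.reshape(n * q, k)
    _, R, piv = sla.qr(Xs, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(Xs.shape) * np.finfo(float).eps
    bad = piv[diag < tol] if (diag < tol).any() else np.array([], int)
    if bad.size:
        names = [designs.coef_names[j] for j in sorted(bad)]
        raise RankDeficiencyError(
            f"fixed-effects design is rank deficient; collinear column(s): {names}"
        )


def gls_beta(
    V: np.ndarray, designs: StackedDesignSet, stats_cache: _SufficientStats | None = None
) -> np.ndarray:
    """Generalized least squares: (sum X'V^-1 X)^-1 sum X'V^-1 y."""
    if stats_cache is None:
        stats_cache = _SufficientStats(designs.X, designs.Y)
    W = np.linalg.inv(V)
    A, c, _ = stats_cache.weighted_moments(W)
    try:
        beta = sla.solve(A, c, assume_a="pos")
    except np.linalg.LinAlgError:
        _check_rank(designs)
        raise
    if not np.all(np.isfinite(beta)):
        _check_rank(designs)
    return beta


def log_likelihood(
    beta: np.ndarray,
    D: np.ndarray,
    omega_variances: np.ndarray,
    designs: StackedDesignSet,
) -> float:
    """Gaussian marginal log-likelihood at given (beta, D, Omega).

    ``sum_i -1/2 [q log 2pi + log|V| + (y_i - X_i beta)' V^-1 (y_i - X_i beta)]``
    with the common V of the balanced design.
    """
    V = marginal_covariance(D, omega_variances)
    cho = sla.cho_factor(V, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    R = designs.Y - designs.X @ np.asarray(beta, float)  # (n, q)
    sol = sla.cho_solve(cho, R.T)  # (q, n)
    quad = float(np.sum(R.T * sol))
    n, q = designs.n, designs.q
    return -0.5 * (n * q * _LOG_2PI + n * logdet + quad)


# --------------------------------------------------------------------------
# parameterization: theta = (log-Cholesky of D, log residual variances)


def _theta_size(p: int) -> int:
    return p * (p + 1) // 2 + p


def theta_to_params(theta: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Unpack theta -> (D, omega_variances); D = L L' with log-diagonal L."""
    theta = np.asarray(theta, float)
    L = np.zeros((p, p))
    idx = 0
    for i in range(p):
        for j in range(i + 1):
            if i == j:
                L[i, j] = np.exp(theta[idx])
            else:
                L[i, j] = theta[idx]
            idx += 1
    omega = np.exp(theta[idx : idx + p])
    return L @ L.T, omega


def params_to_theta(D: np.ndarray, omega_variances: np.ndarray) -> np.ndarray:
    """Pack (D, omega) into the unconstrained vector (inverse of unpack)."""
    D = np.asarray(D, float)
    p = D.shape[0]
    # ridge for exactly-singular D so the log-Cholesky exists
    evals = np.linalg.eigvalsh(D)
    if evals.min() < 1e-8:
        D = D + (1e-8 - min(evals.min(), 0.0)) * np.eye(p)
    L = np.linalg.cholesky(D)
    out = []
    for i in range(p):
        for j in range(i + 1):
            out.append(np.log(L[i, j]) if i == j else L[i, j])
    out.extend(np.log(np.asarray(omega_variances, float)))
    return np.array(out)


# --------------------------------------------------------------------------
# model / results objects


class MLMMResults:
    """Maximum-likelihood fit of the multivariate longitudinal model.

    Carries the fixed-effect estimates with their covariance, the estimated
    random-intercept covariance ``D`` and residual variances, the maximized
    log-likelihood and convergence diagnostics.  ``summary()`` renders a
    text table; ``to_classifier()`` builds the discriminant allocation rule
    from the fit.
    """

    def __init__(
        self,
        spec: ModelSpec,
        beta: np.ndarray,
        D: np.ndarray,
        omega_variances: np.ndarray,
        loglik: float,
        converged: bool,
        n_iter: int,
        vcov_beta: np.ndarray,
        n_subjects: int,
        group_counts: dict[int, int],
        theta: np.ndarray | None = None,
        message: str = "",
    ):
        self.spec = spec
        self.beta = pd.Series(beta, index=list(spec.coef_names), name="estimate")
        self.D = pd.DataFrame(
            D, index=list(spec.response_markers), columns=list(spec.response_markers)
        )
        self.omega_variances = pd.Series(
            omega_variances, index=list(spec.response_markers), name="sigma2"
        )
        self.loglik = float(loglik)
        self.converged = bool(converged)
        self.n_iter = int(n_iter)
        self.vcov_beta = pd.DataFrame(
            vcov_beta, index=list(spec.coef_names), columns=list(spec.coef_names)
        )
        self.n_subjects = int(n_subjects)
        self.group_counts = {int(k): int(v) for k, v in group_counts.items()}
        self.theta = None if theta is None else np.asarray(theta, float)
        self.message = message

    # -- derived quantities ----------------------------------------------

    @property
    def bse(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self.vcov_beta.to_numpy())),
            index=self.beta.index,
            name="se",
        )

    def marginal_covariance(self) -> pd.DataFrame:
        V = marginal_covariance(
            self.D.to_numpy(), self.omega_variances.to_numpy()
        )
        names = [f"{m}@v{v}" for m in self.spec.response_markers for v in (1, 2)]
        return pd.DataFrame(V, index=names, columns=names)

    def sample_priors(self) -> tuple[float, float]:
        """(pi1, pi2) from the fitted sample's group proportions."""
        n1 = self.group_counts.get(1, 0)
        n2 = self.group_counts.get(2, 0)
        tot = n1 + n2
        if n1 == 0 or n2 == 0:
            raise ValueError("both groups must be present to form sample priors")
        return n1 / tot, n2 / tot

    def to_classifier(self, priors: tuple[float, float] | None = None):
        from .discriminant import LongitudinalDiscriminant

        return LongitudinalDiscriminant(self, priors=priors)

    def summary(self) -> str:
        z = self.beta / self.bse
        pvals = 2.0 * stats.norm.sf(np.abs(z))
        lines = [
            "Multivariate longitudinal mixed model (ML)",
            "=" * 66,
            f"subjects: {self.n_subjects}   responses/subject: {self.spec.q}   "
            f"log-likelihood: {self.loglik:.4f}",
            f"converged: {self.converged} (iterations: {self.n_iter})",
            "-" * 66,
            f"{'coef':<16}{'estimate':>12}{'se':>10}{'z':>9}{'P>|z|':>9}",
        ]
        for name in self.beta.index:
            lines.append(
                f"{name:<16}{self.beta[name]:>12.4f}{self.bse[name]:>10.4f}"
                f"{z[name]:>9.2f}{pvals[list(self.beta.index).index(name)]:>9.3f}"
            )
        lines.append("-" * 66)
        lines.append("random-intercept covariance D:")
        lines.append(self.D.round(4).to_string())
        lines.append("residual variances (per biomarker):")
        lines.append(self.omega_variances.round(4).to_string())
        return "\n".join(lines)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "beta": {k: float(v) for k, v in self.beta.items()},
            "D": self.D.to_numpy().tolist(),
            "omega_variances": {k: float(v) for k, v in self.omega_variances.items()},
            "loglik": self.loglik,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "vcov_beta": self.vcov_beta.to_numpy().tolist(),
            "n_subjects": self.n_subjects,
            "group_counts": {str(k): v for k, v in self.group_counts.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLMMResults":
        spec = ModelSpec.from_dict(d["spec"])
        return cls(
            spec=spec,
            beta=np.array([d["beta"][k] for k in spec.coef_names]),
            D=np.asarray(d["D"], float),
            omega_variances=np.array(
                [d["omega_variances"][m] for m in spec.response_markers]
            ),
            loglik=d["loglik"],
            converged=d["converged"],
            n_iter=d["n_iter"],
            vcov_beta=np.asarray(d["vcov_beta"], float),
            n_subjects=d["n_subjects"],
            group_counts={int(k): v for k, v in d["group_counts"].items()},
        )


class MultivariateLongitudinalModel:
    """Model object binding a cohort to a :class:`ModelSpec`.

    Statsmodels-style usage::

        model = MultivariateLongitudinalModel(cohort)      # default 4-marker spec
        res = model.fit()
        print(res.summary())
        clf = res.to_classifier()
    """

    def __init__(self, cohort: CohortTable, spec: ModelSpec | None = None):
        self.spec = spec if spec is not None else ModelSpec()
        self.cohort = cohort
        self.designs = build_design(cohort, self.spec)
        _check_rank(self.designs)
        self._stats = _SufficientStats(self.designs.X, self.designs.Y)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        spec: ModelSpec | None = None,
        column_map=None,
        drop_incomplete: bool = False,
    ) -> "MultivariateLongitudinalModel":
        table = CohortTable.from_dataframe(
            df, column_map=column_map, drop_incomplete=drop_incomplete
        )
        return cls(table, spec=spec)

    @classmethod
    def from_designs(cls, designs: StackedDesignSet) -> "MultivariateLongitudinalModel":
        obj = cls.__new__(cls)
        obj.spec = designs.spec
        obj.cohort = None
        obj.designs = designs
        _check_rank(designs)
        obj._stats = _SufficientStats(designs.X, designs.Y)
        return obj

    # -- likelihood machinery --------------------------------------------

    def _profile(self, theta: np.ndarray):
        """(beta_hat, profile loglik, X'WX) at covariance parameters theta."""
        p = self.spec.n_markers
        D, omega = theta_to_params(theta, p)
        V = marginal_covariance(D, omega, check=False)
        try:
            cho = sla.cho_factor(V, lower=True)
        except np.linalg.LinAlgError:
            return None, -np.inf, None
        logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
        W = sla.cho_solve(cho, np.eye(V.shape[0]))
        A, c, yy = self._stats.weighted_moments(W)
        try:
            beta = sla.solve(A, c, assume_a="pos")
        except np.linalg.LinAlgError:
            return None, -np.inf, None
        quad = yy - c @ beta
        n, q = self.designs.n, self.designs.q
        ll = -0.5 * (n * q * _LOG_2PI + n * logdet + quad)
        return beta, ll, A

    def _start_theta(self) -> np.ndarray:
        """Moment-based starting values from OLS residual covariance."""
        p = self.spec.n_markers
        beta0 = gls_beta(np.eye(self.designs.q), self.designs, self._stats)
        R = self.designs.Y - self.designs.X @ beta0
        S = R.T @ R / max(self.designs.n, 1)  # (q, q)
        D0 = np.empty((p, p))
        omega0 = np.empty(p)
        for m in range(p):
            i0, i1 = 2 * m, 2 * m + 1
            var_m = 0.5 * (S[i0, i0] + S[i1, i1])
            d_m = S[i0, i1]
            d_m = np.clip(d_m, 0.05 * var_m, 0.95 * var_m)
            D0[m, m] = d_m
            omega0[m] = max(var_m - d_m, 0.05 * var_m)
            for m2 in range(m):
                j0, j1 = 2 * m2, 2 * m2 + 1
                cross = 0.25 * (S[i0, j0] + S[i0, j1] + S[i1, j0] + S[i1, j1])
                D0[m, m2] = D0[m2, m] = cross
        # shrink off-diagonals until PD
        for shrink in (1.0, 0.7, 0.4, 0.1, 0.0):
            Dc = np.diag(np.diag(D0)) + shrink * (D0 - np.diag(np.diag(D0)))
            if np.linalg.eigvalsh(Dc).min() > 1e-10:
                D0 = Dc
                break
        return params_to_theta(D0, omega0)

    def loglike(self, theta: np.ndarray, beta: np.ndarray | None = None) -> float:
        p = self.spec.n_markers
        D, omega = theta_to_params(np.asarray(theta, float), p)
        if beta is None:
            _, ll, _ = self._profile(np.asarray(theta, float))
            return ll
        return log_likelihood(beta, D, omega, self.designs)

    def fit(
        self,
        start: np.ndarray | MLMMResults | None = None,
        maxiter: int = 500,
        gtol: float = 1e-7,
        ftol: float = 1e-11,
    ) -> MLMMResults:
        """Maximize the profile likelihood; never raises on non-convergence
        (the results carry ``converged=False`` and the optimizer message)."""
        if isinstance(start, MLMMResults):
            theta0 = params_to_theta(
                start.D.to_numpy(), start.omega_variances.to_numpy()
            )
        elif start is not None:
            theta0 = np.asarray(start, float)
        else:
            theta0 = self._start_theta()

        def nll(theta):
            _, ll, _ = self._profile(theta)
            return -ll if np.isfinite(ll) else 1e12

        res = optimize.minimize(
            nll,
            theta0,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": ftol, "gtol": gtol},
        )
        if not res.success:
            # line searches occasionally stall on the numerical gradient
            # near the optimum; restart with a coarser finite-difference step
            retry = optimize.minimize(
                nll,
                res.x,
                method="L-BFGS-B",
                options={
                    "maxiter": maxiter,
                    "ftol": ftol,
                    "gtol": gtol,
                    "eps": 1e-6,
                },
            )
            if retry.fun <= res.fun:
                res = retry
        beta, ll, A = self._profile(res.x)
        if beta is None:
            raise CovarianceError("optimizer terminated at a non-PD covariance")
        p = self.spec.n_markers
        D, omega = theta_to_params(res.x, p)
        vcov = np.linalg.inv(A)
        groups = self.designs.groups
        counts = {g: int(np.sum(groups == g)) for g in np.unique(groups)}
        converged = bool(res.success) or np.max(np.abs(res.jac)) < 1e-3
        if not converged:
            warnings.warn(
                f"mixed-model fit did not converge: {res.message}", RuntimeWarning
            )
        return MLMMResults(
            spec=self.spec,
            beta=beta,
            D=D,
            omega_variances=omega,
            loglik=ll,
            converged=converged,
            n_iter=int(res.nit),
            vcov_beta=vcov,
            n_subjects=self.designs.n,
            group_counts=counts,
            theta=res.x,
            message=str(res.message),
        )


def fit(
    designs: StackedDesignSet,
    spec: ModelSpec | None = None,
    **options,
) -> MLMMResults:
    """Functional front-end: ML fit from an assembled design set."""
    if spec is not None and spec != designs.spec:
        raise ValueError("spec does not match the one the designs were built with")
    return MultivariateLongitudinalModel.from_designs(designs).fit(**options)
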
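"""Allocation of subjects to non-GDM vs GDM from longitudinal biomarkers.

After the mixed model is fitted, subject *i* with stacked response ``y_i``
is allocated by the linear discriminant for two Gaussian populations with a
common covariance ``V_i = Z_i D Z_i' + Omega_i``:

    L_i = (mu_1i - mu_2i)' V_i^-1 (y_i - (mu_1i + mu_2i) / 2)

where ``mu_gi = X_i^(g) beta`` is the model-implied mean with the group
indicator forced to g and all other covariates at the subject's observed
values.  The subject goes to population 1 (non-GDM) iff ``L_i >=
ln(pi2 / pi1)`` -- ties at the threshold stay in population 1 -- and to
population 2 (GDM) otherwise.  This is exactly the Bayes rule for the
equal-covariance Gaussian model with prior proportions (pi1, pi2), so
larger scores favor non-GDM.  Priors default to the fitted sample's group
proportions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy import special

from .cohort import GDM, NON_GDM, CohortTable
from .mlmm import (
    MLMMResults,
    ModelSpec,
    MultivariateLongitudinalModel,
    StackedDesignSet,
    build_design,
    marginal_covariance,
)

logger = logging.getLogger(__name__)


class StratificationError(ValueError):
    """A cross-validation training split lacks one of the groups."""


def discriminant_score(
    y: np.ndarray, mu1: np.ndarray, mu2: np.ndarray, V: np.ndarray
) -> float | np.ndarray:
    """Linear discriminant score L; larger values favor population 1.

    Accepts a single q-vector or an (n, q) batch for ``y``/``mu1``/``mu2``.
    """
    y = np.atleast_2d(np.asarray(y, float))
    mu1 = np.atleast_2d(np.asarray(mu1, float))
    mu2 = np.atleast_2d(np.asarray(mu2, float))
    cho = sla.cho_factor(np.asarray(V, float), lower=True)
    diff = mu1 - mu2
    centered = y - 0.5 * (mu1 + mu2)
    a = sla.cho_solve(cho, diff.T)  # (q, n)
    L = np.sum(centered.T * a, axis=0)
    return float(L[0]) if L.size == 1 else L


def allocation_threshold(pi1: float, pi2: float) -> float:
    if not (pi1 > 0 and pi2 > 0):
        raise ValueError("priors must be strictly positive")
    if not np.isclose(pi1 + pi2, 1.0):
        raise ValueError("priors must sum to 1")
    return float(np.log(pi2 / pi1))


def allocate(L, pi1: float, pi2: float):
    """Group label from a discriminant score: 1 iff L >= ln(pi2/pi1)."""
    thr = allocation_threshold(pi1, pi2)
    L = np.asarray(L, float)
    out = np.where(L >= thr, NON_GDM, GDM)
    return int(out) if out.ndim == 0 else out


def posterior(
    y: np.ndarray,
    mu1: np.ndarray,
    mu2: np.ndarray,
    V: np.ndarray,
    pi1: float,
    pi2: float,
):
    """Posterior group probabilities (p1, p2) under the equal-covariance
    Gaussian model; computed in log space, so no NaN for |L| up to ~700.

    Identity with the score: p1/p2 = exp(L) * pi1/pi2.
    """
    allocation_threshold(pi1, pi2)  # validates priors
    L = discriminant_score(y, mu1, mu2, V)
    # p1 = 1 / (1 + exp(-(L + log(pi1/pi2))))
    eta = np.asarray(L, float) + np.log(pi1 / pi2)
    p1 = special.expit(eta)
    p2 = 1.0 - p1
    if np.ndim(L) == 0:
        return float(p1), float(p2)
    return p1, p2


@dataclass
class ClassificationResult:
    """Per-subject scores, labels and posteriors.

    ``table`` columns: subject_id, group (true label), score, label
    (allocated), posterior1, posterior2.  ``provenance`` records whether
    scores are resubstitution or out-of-fold cross-validated.
    """

    table: pd.DataFrame
    provenance: str
    pi1: float
    pi2: float

    @property
    def scores(self) -> np.ndarray:
        return self.table["score"].to_numpy()

    @property
    def true_groups(self) -> np.ndarray:
        return self.table["group"].to_numpy(int)

    @property
    def labels(self) -> np.ndarray:
        return self.table["label"].to_numpy(int)

    @property
    def threshold(self) -> float:
        return allocation_threshold(self.pi1, self.pi2)


class LongitudinalDiscriminant:
    """Allocation rule built from a fitted :class:`~gdmlda.mlmm.MLMMResults`.

    Parameters
    ----------
    results : MLMMResults
        A (converged) maximum-likelihood fit.
    priors : (pi1, pi2), optional
        Prior proportions of non-GDM and GDM; defaults to the fitted
        sample's group proportions.
    """

    def __init__(self, results: MLMMResults, priors: tuple[float, float] | None = None):
        self.results = results
        self.spec: ModelSpec = results.spec
        if priors is None:
            priors = results.sample_priors()
        self.pi1, self.pi2 = float(priors[0]), float(priors[1])
        allocation_threshold(self.pi1, self.pi2)  # validate
        self.V = marginal_covariance(
            results.D.to_numpy(), results.omega_variances.to_numpy()
        )
        self._beta = results.beta.to_numpy()

    @property
    def threshold(self) -> float:
        return allocation_threshold(self.pi1, self.pi2)

    # -- means and scores -------------------------------------------------

    def _group_designs(self, designs: StackedDesignSet):
        """Copies of X with the group indicator forced to 0 (X1) and 1 (X2).

        The design is block-structured: marker m's columns are nonzero only
        in marker m's own two rows, so the indicator is toggled per block.
        """
        spec = designs.spec
        terms = spec.terms
        n_terms = len(terms)
        jg = terms.index("group")
        jt_inter = terms.index("group:time") if "group:time" in terms else None
        X1 = designs.X.copy()
        X2 = designs.X.copy()
        for jm in range(spec.n_markers):
            rows = slice(2 * jm, 2 * jm + 2)
            col = jm * n_terms + jg
            X1[:, rows, col] = 0.0
            X2[:, rows, col] = 1.0
            if jt_inter is not None:
                icol = jm * n_terms + jt_inter
                X1[:, rows, icol] = 0.0
                # interaction = group * time; time is 0 at visit 1, 1 at visit 2
                X2[:, 2 * jm, icol] = 0.0
                X2[:, 2 * jm + 1, icol] = 1.0
        return X1, X2

    def conditional_group_means(self, designs: StackedDesignSet):
        """Model-implied (mu1, mu2) per subject, (n, q) each.

        Functions of X only: the subject's observed responses never enter.
        """
        X1, X2 = self._group_designs(designs)
        return X1 @ self._beta, X2 @ self._beta

    def scores(self, designs: StackedDesignSet) -> np.ndarray:
        mu1, mu2 = self.conditional_group_means(designs)
        return np.asarray(discriminant_score(designs.Y, mu1, mu2, self.V))

    # -- classification ----------------------------------------------------

    def classify_designs(
        self, designs: StackedDesignSet, provenance: str = "resubstitution"
    ) -> ClassificationResult:
        mu1, mu2 = self.conditional_group_means(designs)
        L = np.atleast_1d(
            np.asarray(discriminant_score(designs.Y, mu1, mu2, self.V))
        )
        labels = allocate(L, self.pi1, self.pi2)
        p1, p2 = posterior(designs.Y, mu1, mu2, self.V, self.pi1, self.pi2)
        table = pd.DataFrame(
            {
                "subject_id": designs.subject_ids,
                "group": designs.groups,
                "score": L,
                "label": np.atleast_1d(labels),
                "posterior1": np.atleast_1d(p1),
                "posterior2": np.atleast_1d(p2),
            }
        )
        return ClassificationResult(
            table=table, provenance=provenance, pi1=self.pi1, pi2=self.pi2
        )

    def classify(self, table: CohortTable) -> ClassificationResult:
        """Resubstitution-style classification of a cohort."""
        designs = build_design(table, self.spec)
        return self.classify_designs(designs, provenance="resubstitution")


def classify_cohort(
    results: MLMMResults,
    table: CohortTable,
    priors: tuple[float, float] | None = None,
) -> ClassificationResult:
    """Functional front-end for resubstitution classification."""
    return LongitudinalDiscriminant(results, priors=priors).classify(table)


def cross_validate(
    table: CohortTable,
    spec: ModelSpec | None = None,
    folds: int = 10,
    seed: int = 0,
    priors: tuple[float, float] | None = None,
) -> ClassificationResult:
    """Stratified k-fold cross-validated classification.

    Each subject is scored by a model fitted without them; priors (when not
    fixed) are the training split's group proportions.  Deterministic given
    the seed.
    """
    from sklearn.model_selection import StratifiedKFold

    if folds < 2:
        raise ValueError("folds must be >= 2")
    if spec is None:
        spec = ModelSpec()
    designs = build_design(table, spec)
    n = designs.n
    groups = designs.groups
    if folds == n:  # leave-one-out
        idx = np.arange(n)
        splits = [(np.delete(idx, i), np.array([i])) for i in range(n)]
    else:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = list(skf.split(np.zeros(n), groups))
    parts = []
    for train_idx, test_idx in splits:
        train_groups = groups[train_idx]
        if len(np.unique(train_groups)) < 2:
            raise StratificationError(
                "a training split contains a single group; reduce folds"
            )
        mask = np.zeros(n, bool)
        mask[train_idx] = True
        model = MultivariateLongitudinalModel.from_designs(designs.subset(mask))
        res = model.fit()
        clf = LongitudinalDiscriminant(res, priors=priors)
        part = clf.classify_designs(
            designs.subset(~mask), provenance="cross-validated"
        )
        parts.append(part.table)
    out = pd.concat(parts, ignore_index=True)
    out = out.sort_values("subject_id", kind="mergesort").reset_index(drop=True)
    if priors is None:
        n2 = int(np.sum(groups == GDM))
        pi2 = n2 / n
        pi1 = 1.0 - pi2
    else:
        pi1, pi2 = priors
    return ClassificationResult(
        table=out, provenance="cross-validated", pi1=pi1, pi2=pi2
    )
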
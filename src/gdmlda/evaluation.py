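"""ROC analysis of discriminant scores.

Orientation convention (important): the discriminant score ``L`` is
oriented so that *larger values favor non-GDM* (population 1); the ROC
positive class is GDM.  The risk marker used throughout this module is
therefore the **negated** score, so that larger risk means more GDM-like.
Getting this wrong silently reports 1 - AUC; every public function here
takes raw discriminant scores plus true group labels and handles the
negation internally.

AUC is the Mann-Whitney estimator (ties count 1/2), identical to the
trapezoidal area under the empirical ROC curve.  Confidence intervals are
DeLong's variance-based normal approximation by default, with a stratified
bootstrap percentile interval as a seeded alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cohort import GDM, NON_GDM


class DegenerateInputError(ValueError):
    """Scores/labels contain a single class or too few observations."""


def _split_risks(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same shape")
    risk = -scores  # larger = more GDM-like
    pos = risk[labels == GDM]
    neg = risk[labels == NON_GDM]
    if pos.size == 0 or neg.size == 0:
        raise DegenerateInputError("both classes must be present")
    return risk, pos, neg


@dataclass
class OperatingPoint:
    name: str
    threshold: float  # on the *score* scale (predict GDM iff score < threshold)
    sensitivity: float
    specificity: float


@dataclass
class ROCResult:
    """Empirical ROC curve of a discriminant-score classifier.

    ``thresholds`` are score cut-offs (ascending); at cut-off *c* a subject
    is called GDM iff score < c (the allocation rule keeps ties at the
    threshold in the non-GDM group).  ``fpr``/``tpr`` are 1-specificity and
    sensitivity at each cut-off.
    """

    thresholds: np.ndarray
    sens: np.ndarray
    spec: np.ndarray
    auc: float
    auc_ci: tuple[float, float] | None = None
    ci_level: float | None = None
    operating_points: dict = field(default_factory=dict)

    @property
    def fpr(self) -> np.ndarray:
        return 1.0 - self.spec


def sens_spec_at(scores, labels, threshold: float) -> tuple[float, float]:
    """Sensitivity/specificity of the rule: GDM iff score < threshold.

    Mirrors the allocation rule's tie handling: a score exactly at the
    threshold is allocated non-GDM.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    is_gdm = labels == GDM
    if is_gdm.all() or (~is_gdm).all():
        raise DegenerateInputError("both classes must be present")
    pred_gdm = scores < threshold
    sens = float(np.mean(pred_gdm[is_gdm]))
    spec = float(np.mean(~pred_gdm[~is_gdm]))
    return sens, spec


def roc_curve(scores, labels) -> ROCResult:
    """Exhaustive-threshold empirical ROC curve (one point per distinct
    score plus both endpoints); AUC by the trapezoidal rule."""
    _split_risks(scores, labels)  # validates
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    # thresholds on the score scale: below the minimum nobody is called
    # GDM; above the maximum everybody is
    uniq = np.unique(scores)
    thresholds = np.concatenate(([-np.inf], uniq, [np.inf]))
    # shift: at threshold equal to a score, that score is non-GDM, so use
    # strictly-greater cut-offs to pick up each distinct point
    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    is_gdm = labels == GDM
    n_pos = is_gdm.sum()
    n_neg = (~is_gdm).sum()
    order = np.argsort(scores, kind="mergesort")
    sorted_scores = scores[order]
    sorted_pos = is_gdm[order]
    cum_pos = np.concatenate(([0], np.cumsum(sorted_pos)))
    cum_all = np.arange(scores.size + 1)
    for i, thr in enumerate(thresholds):
        # number with score < thr
        idx = np.searchsorted(sorted_scores, thr, side="left")
        tp = cum_pos[idx]
        fp = cum_all[idx] - tp
        sens[i] = tp / n_pos
        spec[i] = 1.0 - fp / n_neg
    # larger threshold -> more called GDM -> sens non-decreasing
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens, fpr))
    return ROCResult(thresholds=thresholds, sens=sens, spec=spec, auc=auc)


def auc_mann_whitney(scores, labels) -> float:
    """AUC = [#(risk_pos > risk_neg) + 1/2 #(ties)] / (n_pos * n_neg),
    computed via midranks (exact, O(n log n))."""
    risk, pos, neg = _split_risks(scores, labels)
    n_pos, n_neg = pos.size, neg.size
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[:n_pos].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _delong_components(pos: np.ndarray, neg: np.ndarray):
    """DeLong structural components V10 (per positive) and V01 (per negative)."""
    # midrank formulation would be faster; direct comparison is O(mn) and
    # transparent, fine at cohort scale
    cmp = (pos[:, None] > neg[None, :]).astype(float)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp.mean(axis=1)
    v01 = cmp.mean(axis=0)
    return v10, v01


def delong_variance(scores, labels) -> tuple[float, float]:
    """(AUC, variance of AUC) by DeLong's structural-components method."""
    _, pos, neg = _split_risks(scores, labels)
    if pos.size < 2 or neg.size < 2:
        raise DegenerateInputError("need >= 2 observations per class")
    v10, v01 = _delong_components(pos, neg)
    auc = float(v10.mean())
    s10 = v10.var(ddof=1)
    s01 = v01.var(ddof=1)
    return auc, float(s10 / pos.size + s01 / neg.size)


def auc_ci(
    scores,
    labels,
    level: float = 0.95,
    method: str = "delong",
    seed: int | None = None,
    n_boot: int = 2000,
) -> tuple[float, float]:
    """Confidence interval for the AUC, truncated to [0, 1].

    ``method="delong"`` (default) uses the normal approximation with the
    DeLong variance; ``method="bootstrap"`` a stratified percentile
    bootstrap (seeded, ``n_boot`` resamples).
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if method == "delong":
        auc, var = delong_variance(scores, labels)
        z = stats.norm.ppf(0.5 + level / 2.0)
        half = z * np.sqrt(var)
        return (max(0.0, auc - half), min(1.0, auc + half))
    if method == "bootstrap":
        _, pos, neg = _split_risks(scores, labels)
        if pos.size < 2 or neg.size < 2:
            raise DegenerateInputError("need >= 2 observations per class")
        if seed is None:
            raise ValueError("bootstrap CI requires a seed")
        rng = np.random.default_rng(seed)
        aucs = np.empty(n_boot)
        for b in range(n_boot):
            bp = pos[rng.integers(0, pos.size, pos.size)]
            bn = neg[rng.integers(0, neg.size, neg.size)]
            ranks = stats.rankdata(np.concatenate([bp, bn]))
            r_pos = ranks[: pos.size].sum()
            aucs[b] = (r_pos - pos.size * (pos.size + 1) / 2.0) / (
                pos.size * neg.size
            )
        lo, hi = np.quantile(aucs, [(1 - level) / 2.0, 0.5 + level / 2.0])
        return (float(max(0.0, lo)), float(min(1.0, hi)))
    raise ValueError(f"unknown CI method {method!r}")


def youden_threshold(scores, labels) -> OperatingPoint:
    """Score threshold maximizing Youden's J = sens + spec - 1.

    Ties in J are broken toward the lower threshold.
    """
    roc = roc_curve(scores, labels)
    j = roc.sens + roc.spec - 1.0
    i = int(np.argmax(j))  # argmax returns the first (lowest-threshold) max
    thr = roc.thresholds[i]
    sens, spec = (
        (roc.sens[i], roc.spec[i])
        if np.isfinite(thr)
        else sens_spec_at(scores, labels, thr)
    )
    return OperatingPoint("youden", float(thr), float(sens), float(spec))


def binormal_auc(m1: float, s1: float, m2: float, s2: float) -> float:
    """Closed-form AUC for two normal classes with a single marker:
    Phi(|m1 - m2| / sqrt(s1^2 + s2^2))."""
    if not (s1 > 0 and s2 > 0):
        raise ValueError("SDs must be > 0")
    return float(stats.norm.cdf(abs(m1 - m2) / np.hypot(s1, s2)))


def evaluate_scores(
    scores,
    labels,
    pi1: float | None = None,
    pi2: float | None = None,
    ci_level: float = 0.95,
    ci_method: str = "delong",
    seed: int | None = None,
    n_boot: int = 2000,
) -> ROCResult:
    """Full ROC analysis: curve, Mann-Whitney AUC, CI and named operating
    points ('bayes' at ln(pi2/pi1) when priors are given; 'youden')."""
    roc = roc_curve(scores, labels)
    roc.auc = auc_mann_whitney(scores, labels)
    roc.auc_ci = auc_ci(
        scores, labels, level=ci_level, method=ci_method, seed=seed, n_boot=n_boot
    )
    roc.ci_level = ci_level
    points = {}
    if pi1 is not None and pi2 is not None:
        thr = float(np.log(pi2 / pi1))
        sens, spec = sens_spec_at(scores, labels, thr)
        points["bayes"] = OperatingPoint("bayes", thr, sens, spec)
    points["youden"] = youden_threshold(scores, labels)
    roc.operating_points = points
    return roc


def plot_roc(results: dict, path: str) -> None:
    """Plot one or more ROC curves ({name: ROCResult}) to a file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, roc in results.items():
        order = np.argsort(roc.fpr, kind="mergesort")
        ax.plot(roc.fpr[order], roc.sens[order], label=f"{name} (AUC={roc.auc:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
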